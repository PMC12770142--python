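"""CT acquisition/reconstruction settings and stability-question groupings.

Ten reconstruction variants (S1..S10) of the same raw acquisition are
modelled: three slice thicknesses, two in-plane matrices, six convolution
kernels and two export routes (scanner console vs PACS).  S2 (1 mm,
1024x1024, B_SHARP_C, console export) is the reference variant; every other
setting differs from it in exactly one factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

KERNELS = (
    "B_SHARP_A",
    "B_SHARP_C",
    "B_VSHARP_D",
    "B_SOFT_C",
    "B_SOFT_F",
    "B_VSOFT_A",
)

SLICE_THICKNESSES_MM = (1, 3, 5)
MATRICES = (512, 1024)
TRANSMISSIONS = ("console", "PACS")


@dataclass(frozen=True)
class AcquisitionSetting:
    """One reconstruction variant of a CT acquisition.

    Parameters
    ----------
    setting_id : str
        Label ``S1``..``S10``.
    slice_thickness_mm : int
        Reconstructed slice thickness, one of 1, 3, 5 mm.
    matrix : int
        In-plane reconstruction matrix, 512 or 1024.
    kernel_id : str
        Convolution kernel identifier (soft..sharp family).
    transmission : str
        ``"console"`` (direct workstation export) or ``"PACS"``.
    """

    setting_id: str
    slice_thickness_mm: int
    matrix: int
    kernel_id: str
    transmission: str

    def __post_init__(self) -> None:
        if self.slice_thickness_mm not in SLICE_THICKNESSES_MM:
            raise ValueError(f"slice_thickness_mm must be one of {SLICE_THICKNESSES_MM}")
        if self.matrix not in MATRICES:
            raise ValueError(f"matrix must be one of {MATRICES}")
        if self.kernel_id not in KERNELS:
            raise ValueError(f"unknown kernel_id {self.kernel_id!r}")
        if self.transmission not in TRANSMISSIONS:
            raise ValueError(f"transmission must be one of {TRANSMISSIONS}")


#: The ten study settings.  Each varies a single factor against S2.
SETTINGS: tuple[AcquisitionSetting, ...] = (
    AcquisitionSetting("S1", 1, 1024, "B_SHARP_C", "PACS"),
    AcquisitionSetting("S2", 1, 1024, "B_SHARP_C", "console"),
    AcquisitionSetting("S3", 3, 1024, "B_SHARP_C", "console"),
    AcquisitionSetting("S4", 5, 1024, "B_SHARP_C", "console"),
    AcquisitionSetting("S5", 1, 1024, "B_SHARP_A", "console"),
    AcquisitionSetting("S6", 1, 1024, "B_VSHARP_D", "console"),
    AcquisitionSetting("S7", 1, 1024, "B_SOFT_C", "console"),
    AcquisitionSetting("S8", 1, 1024, "B_SOFT_F", "console"),
    AcquisitionSetting("S9", 1, 1024, "B_VSOFT_A", "console"),
    AcquisitionSetting("S10", 1, 512, "B_SHARP_C", "console"),
)

SETTINGS_BY_ID: Mapping[str, AcquisitionSetting] = {s.setting_id: s for s in SETTINGS}

REFERENCE_SETTING_ID = "S2"
REFERENCE_SETTING = SETTINGS_BY_ID[REFERENCE_SETTING_ID]


@dataclass(frozen=True)
class SettingGroupPlan:
    """Maps each stability question to the settings that isolate it.

    Every group contains the reference S2 plus the settings differing from
    it only in the factor under study, so a feature's ICC within a group
    measures the impact of that factor alone.
    """

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, ids in self.groups.items():
            unknown = [i for i in ids if i not in SETTINGS_BY_ID]
            if unknown:
                raise ValueError(f"group {name!r} references unknown settings {unknown}")
            if REFERENCE_SETTING_ID not in ids:
                raise ValueError(f"group {name!r} must contain the reference {REFERENCE_SETTING_ID}")
            if len(set(ids)) != len(ids):
                raise ValueError(f"group {name!r} has duplicate settings")


DEFAULT_GROUP_PLAN = SettingGroupPlan(
    groups={
        "slice_thickness": ("S2", "S3", "S4"),
        "matrix": ("S2", "S10"),
        "kernel": ("S2", "S5", "S6", "S7", "S8", "S9"),
        "transmission": ("S1", "S2"),
    }
)
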