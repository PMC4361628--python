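"""DSC acquisition protocol description."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of the dynamic susceptibility contrast sequence.

    Defaults mirror a monthly 3T MS perfusion protocol: single-shot EPI,
    TR = 1.92 s, 50 dynamic volumes with the contrast injection starting at
    the 10th image (0-based volume index 9), 27 contiguous slices acquired
    sequentially ascending, 1.9 x 1.9 x 4 mm voxels.

    ``te`` enters the monoexponential signal-concentration relation
    S = S0 * exp(-te * C).  With the package's unit convention (the
    concentration-conversion constant is fixed at 1 and curve areas live on
    the CBV scale, ~5-12), only the product of echo time, relaxivity and
    concentration is identifiable, and ``te`` plays the role of the
    effective contrast scale.  The default 0.15 yields peak white-matter
    signal drops of ~25-35%, matching the contrast-to-noise of a standard
    3T DSC exam.
    """

    tr: float = 1.92
    te: float = 0.15
    n_volumes: int = 50
    bolus_start_index: int = 9
    n_slices: int = 27
    slice_order: str = "sequential_ascending"
    voxel_size: tuple[float, float, float] = field(default=(1.9, 1.9, 4.0))

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.te <= 0:
            raise ValueError("te must be positive")
        if not (0 < self.bolus_start_index < self.n_volumes):
            raise ValueError("bolus_start_index must lie strictly inside the series")
        if self.slice_order != "sequential_ascending":
            raise ValueError(f"unsupported slice order: {self.slice_order!r}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")

    @property
    def bolus_start_time(self) -> float:
        """Nominal bolus arrival in seconds: bolus_start_index * tr."""
        return self.bolus_start_index * self.tr
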