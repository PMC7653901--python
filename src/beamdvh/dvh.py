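"""Dose-volume histogram data model and metric extraction.

Cumulative DVHs are stored in *dose-quantile* form: for a fixed volume grid
v = Δv, 2Δv, ..., 1.0 the curve records the dose ``D_v`` such that a fraction
``v`` of the organ receives at most ``D_v``.  Resampling every structure onto
the same percentage-volume grid (0.1% bins by default) makes curves of
different organs and patients directly comparable and of equal length, which
is what the sequence regressor in :mod:`beamdvh.model` consumes.

The conventional clinical form — volume fraction receiving at least each dose
level — is available as :class:`DoseBinnedDVH`, with exact conversions in both
directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DVHCurve",
    "DoseBinnedDVH",
    "BeamDVHSet",
    "GANTRY_ANGLES",
    "STRUCTURE_VOCABULARY",
    "quantile_from_voxel_doses",
    "to_quantile",
    "to_dose_binned",
    "dose_at_relative_volume",
    "dose_at_absolute_volume",
    "mean_dose",
    "max_dose",
]

#: Gantry angles (degrees) of the nine equally spaced conformal input beams,
#: ordered by field index FI = 1..9.
GANTRY_ANGLES: tuple = (160, 120, 80, 40, 0, 320, 280, 240, 200)

N_BEAMS = len(GANTRY_ANGLES)

#: Organ-at-risk labels accepted by the pipeline.  Cropped variants (organ
#: minus PTV overlap) carry the same label; cropping happens upstream.
STRUCTURE_VOCABULARY = frozenset(
    {
        "brainstem",
        "brainstem_prv",
        "spinal_cord",
        "spinal_cord_prv",
        "optic_chiasm",
        "optic_nerve_l",
        "optic_nerve_r",
        "lens_l",
        "lens_r",
        "parotid_l",
        "parotid_r",
        "larynx",
        "temporal_lobe_l",
        "temporal_lobe_r",
    }
)

VALID_SOURCES = ("beam", "plan", "predicted")

_MONO_TOL = 1e-9


def _grid_length(dv: float) -> int:
    n = round(1.0 / dv)
    if n < 2 or abs(n * dv - 1.0) > 1e-9:
        raise ValueError(f"dv={dv!r} does not evenly divide the unit volume")
    return n


@dataclass(frozen=True)
class DVHCurve:
    """A cumulative DVH in dose-quantile form on a fixed volume grid.

    ``doses[i]`` is the dose (Gy) below which a fraction ``(i+1)*dv`` of the
    organ volume lies; the grid is closed at v = 1.0 so the maximum dose is
    always represented.
    """

    structure_id: str
    doses: np.ndarray
    dv: float = 0.001
    total_volume_cc: Optional[float] = None
    source: str = "plan"

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        n = _grid_length(self.dv)
        if doses.ndim != 1 or doses.size != n:
            raise ValueError(
                f"curve '{self.structure_id}': expected {n} grid points for "
                f"dv={self.dv}, got {doses.size}"
            )
        if not np.all(np.isfinite(doses)):
            raise ValueError(f"curve '{self.structure_id}': invalid dose (non-finite)")
        if np.any(doses < 0):
            raise ValueError(f"curve '{self.structure_id}': invalid dose (negative)")
        if np.any(np.diff(doses) < -_MONO_TOL):
            raise ValueError(
                f"curve '{self.structure_id}': doses must be non-decreasing "
                "along the volume grid"
            )
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.total_volume_cc is not None and self.total_volume_cc <= 0:
            raise ValueError("total_volume_cc must be positive")
        # tolerate float round-off but store a genuinely monotone array
        doses = np.maximum.accumulate(doses)
        doses.setflags(write=False)
        object.__setattr__(self, "doses", doses)

    @property
    def n_bins(self) -> int:
        return self.doses.size

    @property
    def volume_grid(self) -> np.ndarray:
        """Volume fractions v = dv, 2dv, ..., 1.0."""
        return np.arange(1, self.n_bins + 1) * self.dv


@dataclass(frozen=True)
class DoseBinnedDVH:
    """Conventional cumulative DVH: volume fraction receiving >= each dose."""

    structure_id: str
    dose_edges: np.ndarray
    volume_fractions: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.dose_edges, dtype=float)
        fracs = np.asarray(self.volume_fractions, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two dose edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if fracs.shape != edges.shape:
            raise ValueError("volume_fractions must match dose_edges in length")
        if np.any(fracs < -_MONO_TOL) or np.any(fracs > 1 + _MONO_TOL):
            raise ValueError("not a cumulative DVH: fractions outside [0, 1]")
        if np.any(np.diff(fracs) > _MONO_TOL):
            raise ValueError("not a cumulative DVH: fractions must be non-increasing")
        if edges[0] == 0.0 and abs(fracs[0] - 1.0) > _MONO_TOL:
            raise ValueError("not a cumulative DVH: fraction at dose 0 must be 1")
        edges.setflags(write=False)
        fracs.setflags(write=False)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_fractions", fracs)


@dataclass(frozen=True)
class BeamDVHSet:
    """The nine per-beam DVH curves of one patient-organ, ordered by field index."""

    patient_id: str
    structure_id: str
    beams: tuple
    gantry_angles: tuple = GANTRY_ANGLES

    def __post_init__(self):
        if len(self.beams) != N_BEAMS:
            raise ValueError(f"expected {N_BEAMS} beam curves, got {len(self.beams)}")
        dv0 = self.beams[0].dv
        n0 = self.beams[0].n_bins
        for b in self.beams:
            if b.dv != dv0 or b.n_bins != n0:
                raise ValueError("all beam curves must share dv and grid length")
        object.__setattr__(self, "beams", tuple(self.beams))

    @property
    def dv(self) -> float:
        return self.beams[0].dv

    @property
    def n_bins(self) -> int:
        return self.beams[0].n_bins

    def dose_matrix(self) -> np.ndarray:
        """(n_bins, 9) array of beam doses; column b is field index b+1."""
        return np.stack([b.doses for b in self.beams], axis=1)


# ---------------------------------------------------------------------------
# constructors / converters


def quantile_from_voxel_doses(
    voxel_doses: Sequence[float],
    dv: float = 0.001,
    structure_id: str = "structure",
    total_volume_cc: Optional[float] = None,
    source: str = "plan",
) -> DVHCurve:
    """Empirical dose-quantile curve of a voxel dose list.

    Uses the lower (inverse-CDF) quantile convention: the value at volume
    fraction v is the order statistic of rank ceil(v * n_voxels).
    """
    x = np.asarray(voxel_doses, dtype=float)
    if x.size == 0:
        raise ValueError("empty structure")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("invalid dose")
    if not 0 < dv <= 0.5:
        raise ValueError("dv must lie in (0, 0.5]")
    n = _grid_length(dv)
    xs = np.sort(x)
    v = np.arange(1, n + 1) * dv
    idx = np.ceil(v * x.size - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, x.size - 1)
    return DVHCurve(
        structure_id=structure_id,
        doses=xs[idx],
        dv=dv,
        total_volume_cc=total_volume_cc,
        source=source,
    )


def to_quantile(
    dvh: DoseBinnedDVH,
    dv: float = 0.001,
    total_volume_cc: Optional[float] = None,
    source: str = "plan",
) -> DVHCurve:
    """Resample a dose-binned cumulative DVH onto the percentage-volume grid.

    Inverts the non-increasing volume-vs-dose curve.  Where a volume level is
    attained exactly at an edge, the lowest such dose is returned; between
    edges the crossing dose is found by linear interpolation.
    """
    n = _grid_length(dv)
    edges = dvh.dose_edges
    below = 1.0 - dvh.volume_fractions  # fraction of volume below each edge
    below = np.maximum.accumulate(np.clip(below, 0.0, 1.0))
    v = np.arange(1, n + 1) * dv
    doses = np.empty(n)
    for i, vi in enumerate(v):
        j = int(np.searchsorted(below, vi - 1e-12, side="left"))
        if j >= edges.size:
            doses[i] = edges[-1]
        elif below[j] <= vi + 1e-12:
            # exact attainment: lowest dose reaching this volume level
            doses[i] = edges[j]
        elif j == 0:
            doses[i] = edges[0]
        else:
            d0, d1 = edges[j - 1], edges[j]
            b0, b1 = below[j - 1], below[j]
            doses[i] = d0 + (vi - b0) / (b1 - b0) * (d1 - d0)
    return DVHCurve(
        structure_id=dvh.structure_id,
        doses=doses,
        dv=dv,
        total_volume_cc=total_volume_cc,
        source=source,
    )


def to_dose_binned(dvh: DVHCurve, dose_edges: Sequence[float]) -> DoseBinnedDVH:
    """Export a quantile curve in the conventional dose-binned form.

    The volume fraction at edge d is the exact fraction of volume grid points
    with dose >= d (each grid point carries mass Δv).
    """
    edges = np.asarray(dose_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("dose_edges must be strictly increasing")
    counts = dvh.n_bins - np.searchsorted(dvh.doses, edges, side="left")
    fracs = np.clip(counts * dvh.dv, 0.0, 1.0)
    return DoseBinnedDVH(
        structure_id=dvh.structure_id, dose_edges=edges, volume_fractions=fracs
    )


# ---------------------------------------------------------------------------
# metrics


def dose_at_relative_volume(dvh: DVHCurve, volume_fraction_at_least: float) -> float:
    """Minimum dose received by the hottest ``volume_fraction_at_least`` of the organ.

    D98 corresponds to ``volume_fraction_at_least=0.98``.  The hottest
    fraction f occupies volume (1-f, 1]; its minimum dose is the curve value
    at the first grid point strictly above v = 1 - f (step convention,
    identical to the order statistic on voxel lists).
    """
    f = volume_fraction_at_least
    if not 0 < f <= 1:
        raise ValueError("volume fraction must lie in (0, 1]")
    v_target = 1.0 - f
    p = v_target / dvh.dv
    idx = int(np.floor(p + 1e-9))  # first grid point with v > v_target
    idx = min(idx, dvh.n_bins - 1)
    return float(dvh.doses[idx])


def dose_at_absolute_volume(dvh: DVHCurve, volume_cc: float) -> float:
    """Minimum dose to the hottest ``volume_cc`` cm³ (e.g. D1cc)."""
    if dvh.total_volume_cc is None:
        raise ValueError("absolute metric requires organ volume")
    if not 0 < volume_cc <= dvh.total_volume_cc:
        raise ValueError("volume_cc must lie in (0, total_volume_cc]")
    return dose_at_relative_volume(dvh, volume_cc / dvh.total_volume_cc)


def mean_dose(dvh: DVHCurve) -> float:
    """Δv-weighted mean dose (equal-mass Riemann sum over the volume grid)."""
    return float(dvh.doses.mean())


def max_dose(dvh: DVHCurve) -> float:
    """Maximum dose: the curve value at v = 1."""
    return float(dvh.doses[-1])
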