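"""Synthetic dosimetric cohorts: nine beam DVHs plus a composite-plan DVH.

Each patient-organ sample emulates the dosimetric situation of a nine-field
conformal plan and the optimized composite plan delivered on top of the same
geometry:

* beam b deposits the quantile curve ``D_v^(b) = A · g_b · v^γ_b`` — a
  monotone power curve with a patient-organ amplitude A (up to the
  prescription scale), a per-beam strength g_b and a per-beam shape γ_b;
* the composite plan is a damped quadratic power mean of the beams,
  ``m_v · (Σ_b u_{b,v} (D_v^(b))²)^½``, where at every volume level the
  weights are the beams' instantaneous dose shares,
  ``u_{b,v} = D_v^(b) / Σ_c D_v^(c)``, and the sparing factor
  ``m_v = lo + (hi − lo) · ρ_v`` with ``ρ_v = mean_b D_v^(b) / max_b D_v^(b)``
  interpolates over the configured sparing range: where one beam dominates
  (ρ small) the optimizer can block that direction and spares aggressively;
  where all beams contribute equally (ρ → 1) little sparing is possible.

Both the weights and the sparing factor are smooth functions of the beam
doses themselves, so in noiseless mode the composite is an exact
deterministic function of the nine input curves: the learnability premise
of beam-informed DVH prediction holds by construction, and a predictor that
fails to recover it is wrong, not data-limited.  Patient-to-patient sparing
variation emerges from the variation of the beam profiles.

Optional additive noise is a smooth low-order random polynomial in v (white
noise would be flattened asymmetrically by the monotone projection).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dvh import BeamDVHSet, DVHCurve, N_BEAMS

__all__ = ["CohortConfig", "Cohort", "generate_patient", "generate_cohort"]

DEFAULT_ORGANS = (
    "brainstem",
    "spinal_cord",
    "optic_chiasm",
    "optic_nerve_l",
    "optic_nerve_r",
    "lens_l",
    "parotid_l",
    "larynx",
)

# beam-curve parameter ranges
_A_RANGE = (0.3, 1.0)        # amplitude as fraction of dose_norm_gy
_G_RANGE = (0.2, 1.0)        # per-beam strength
_GAMMA_RANGE = (0.5, 3.0)    # per-beam shape exponent
_Q = 2.0                     # power-mean order of the composite



@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    organs: Tuple[str, ...] = DEFAULT_ORGANS
    dv: float = 0.001
    dose_norm_gy: float = 70.0
    noise_sd_gy: float = 0.0
    sparing_range: Tuple[float, float] = (0.5, 0.9)
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.noise_sd_gy < 0:
            raise ValueError("noise_sd_gy must be >= 0")
        lo, hi = self.sparing_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("sparing_range must lie within (0, 1]")


def _compose(beam_doses: np.ndarray, sparing_range: Tuple[float, float]) -> np.ndarray:
    """Deterministic composite curve from the (n_bins, 9) beam dose matrix.

    Quadratic power mean with instantaneous dose-share weights, damped by a
    volume-dependent sparing factor driven by beam concentration: the more a
    single beam dominates at a dose level, the harder the optimizer spares.
    """
    lo, hi = sparing_range
    total = beam_doses.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    u = beam_doses / safe[:, None]
    pm = np.sqrt(np.sum(u * beam_doses ** _Q, axis=1))
    rho = beam_doses.mean(axis=1) / np.maximum(beam_doses.max(axis=1), 1e-300)
    m = lo + (hi - lo) * rho
    return np.where(total > 0, m * pm, 0.0)


def generate_patient(
    config: CohortConfig,
    organ: str,
    rng: np.random.Generator,
    patient_id: str = "P000",
) -> Tuple[BeamDVHSet, DVHCurve, Dict[str, float]]:
    """One patient-organ sample: beam set, composite plan curve, latent record."""
    n = round(1.0 / config.dv)
    v = np.arange(1, n + 1) * config.dv
    A = rng.uniform(*_A_RANGE) * config.dose_norm_gy
    g = rng.uniform(*_G_RANGE, size=N_BEAMS)
    gamma = rng.uniform(*_GAMMA_RANGE, size=N_BEAMS)
    beam_doses = A * g[None, :] * np.power(v[:, None], gamma[None, :])  # (n, 9)
    composite = _compose(beam_doses, config.sparing_range)
    # latent bookkeeping: dose-share weights and sparing factor at v = 1,
    # where the beam doses reach their maxima A*g_b
    u = g / g.sum()
    rho_top = g.mean() / g.max()
    m = config.sparing_range[0] + (
        config.sparing_range[1] - config.sparing_range[0]
    ) * rho_top
    if config.noise_sd_gy > 0:
        coeffs = rng.standard_normal(4)
        poly = np.polynomial.polynomial.polyval(v, coeffs)
        rms = np.sqrt(np.mean(poly ** 2))
        if rms > 0:
            composite = composite + config.noise_sd_gy * poly / rms
    composite = np.maximum.accumulate(np.clip(composite, 0.0, None))
    beams = tuple(
        DVHCurve(
            structure_id=organ,
            doses=beam_doses[:, b],
            dv=config.dv,
            source="beam",
        )
        for b in range(N_BEAMS)
    )
    beam_set = BeamDVHSet(patient_id=patient_id, structure_id=organ, beams=beams)
    plan = DVHCurve(structure_id=organ, doses=composite, dv=config.dv, source="plan")
    latent = {"patient_id": patient_id, "structure_id": organ, "A": A, "m": m}
    for b in range(N_BEAMS):
        latent[f"g{b + 1}"] = g[b]
        latent[f"gamma{b + 1}"] = gamma[b]
        latent[f"u{b + 1}"] = u[b]
    return beam_set, plan, latent


@dataclass
class Cohort:
    """A generated cohort, split by patient into train and test subsets."""

    train: List[Tuple[BeamDVHSet, DVHCurve]]
    test: List[Tuple[BeamDVHSet, DVHCurve]]
    latents: pd.DataFrame
    config: CohortConfig

    @property
    def train_patients(self) -> List[str]:
        return sorted({bs.patient_id for bs, _ in self.train})

    @property
    def test_patients(self) -> List[str]:
        return sorted({bs.patient_id for bs, _ in self.test})

    def write(self, out_dir, format: str = "csv") -> Dict[str, Path]:
        """Write train/test DVH sets (dvh_core schema) and the latent sidecar."""
        from .io import write_dvh_set, records_from_samples

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for split, samples in (("train", self.train), ("test", self.test)):
            path = out_dir / f"cohort_{split}.{format}"
            write_dvh_set(records_from_samples(samples), path, format=format)
            paths[split] = path
        lat_path = out_dir / "latents.csv"
        self.latents.to_csv(lat_path, index=False, float_format="%.12g")
        paths["latents"] = lat_path
        return paths


def generate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Generate a full cohort, deterministically for a fixed config seed.

    The train/test split is by patient — every organ of one patient lands in
    the same subset — at the configured 80/20 proportion.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n_train = round(config.train_fraction * config.n_patients)
    width = max(3, len(str(config.n_patients)))
    train: List[Tuple[BeamDVHSet, DVHCurve]] = []
    test: List[Tuple[BeamDVHSet, DVHCurve]] = []
    latents: List[Dict[str, float]] = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:0{width}d}"
        bucket = train if p < n_train else test
        for organ in config.organs:
            beam_set, plan, latent = generate_patient(config, organ, rng, pid)
            bucket.append((beam_set, plan))
            latents.append(latent)
    return Cohort(
        train=train, test=test, latents=pd.DataFrame(latents), config=config
    )
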