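"""Replicate expression datasets with biological and technical uncertainty.

Six uncertainty sources are emulated, mirroring how variability enters a
stimulus-response caRNA-seq experiment:

========================  =======================  ==========================
source                    form                     default distribution
========================  =======================  ==========================
TF amplitude              TF * (1 + eps)           eps ~ N(0, 4e-4)
gene response time        t + eps (curve shift)    eps ~ N(0, 25) min^2
kinetic params Kd/ksyn/   param * exp(eps)         eps ~ N(0, 4e-4)
kproc
basal activity k0         k0 + eps                 eps ~ U(0, 0.02)
sample preparation time   t + eps (read-out)       eps ~ N(0, 25) min^2
assay measurement         y + eps                  eps ~ N(0, 0.01 * y^2)
========================  =======================  ==========================

Biology-side draws (amplitude, response time, kinetics, k0) are made per
gene, condition and replicate; the sample-preparation shift is drawn per
collected sample (condition, timepoint, replicate) and shared across genes
measured in that sample; measurement noise is per value.  The nominal t=0
sample comes from unstimulated cells at steady state and is never
time-shifted.  Shifted read-out times are clamped to [0, 80] min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, InvalidInputError
from .enumeration import GRSCatalog, PerturbationPanel, panel_response
from .grs_core import DEFAULT_TIMEPOINTS, gate_activity

__all__ = [
    "NoiseConfig",
    "ReplicateDataset",
    "generate_noisy_dataset",
    "empirical_variance",
    "UNCERTAINTY_LEVELS",
]

#: Per-source variance multipliers for the five overall uncertainty levels,
#: keyed by the overall-uncertainty label.
UNCERTAINTY_LEVELS = {
    "0.21x": {"tf_amplitude": 0.25, "response_time": 0.25, "kinetic": 0.25,
              "k0": 0.5, "prep_time": 0.25, "measurement": 0.25},
    "0.53x": {"tf_amplitude": 0.5, "response_time": 0.56, "kinetic": 0.5,
              "k0": 0.75, "prep_time": 0.56, "measurement": 0.56},
    "1x": {"tf_amplitude": 1.0, "response_time": 1.0, "kinetic": 1.0,
           "k0": 1.0, "prep_time": 1.0, "measurement": 1.0},
    "1.64x": {"tf_amplitude": 1.1, "response_time": 2.0, "kinetic": 1.1,
              "k0": 1.05, "prep_time": 2.0, "measurement": 1.1},
    "2.66x": {"tf_amplitude": 1.45, "response_time": 4.0, "kinetic": 1.45,
              "k0": 1.2, "prep_time": 4.0, "measurement": 1.4},
}


@dataclass(frozen=True)
class NoiseConfig:
    """Variance parameters of the six uncertainty sources (base level)."""

    tf_amplitude_var: float = 4.0e-4
    response_time_var: float = 25.0
    kinetic_var: float = 4.0e-4
    k0_uniform_max: float = 0.02
    prep_time_var: float = 25.0
    measurement_var: float = 0.01  # variance is measurement_var * y^2
    level: str = "1x"

    def __post_init__(self) -> None:
        for name in ("tf_amplitude_var", "response_time_var", "kinetic_var",
                     "k0_uniform_max", "prep_time_var", "measurement_var"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def at_level(cls, level: str) -> "NoiseConfig":
        """Base configuration scaled by the named overall-uncertainty level."""
        if level not in UNCERTAINTY_LEVELS:
            raise ConfigurationError(
                f"unknown uncertainty level {level!r}; options: {sorted(UNCERTAINTY_LEVELS)}"
            )
        m = UNCERTAINTY_LEVELS[level]
        base = cls()
        return cls(
            tf_amplitude_var=base.tf_amplitude_var * m["tf_amplitude"],
            response_time_var=base.response_time_var * m["response_time"],
            kinetic_var=base.kinetic_var * m["kinetic"],
            k0_uniform_max=base.k0_uniform_max * m["k0"],
            prep_time_var=base.prep_time_var * m["prep_time"],
            measurement_var=base.measurement_var * m["measurement"],
            level=level,
        )

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, level="none")


@dataclass(frozen=True)
class ReplicateDataset:
    """Gene x condition x timepoint x replicate expression values (RPKM)."""

    values: np.ndarray  # (genes, conditions, timepoints, replicates)
    timepoints: tuple[float, ...]
    gene_labels: tuple[str, ...]
    condition_signatures: tuple[str, ...]
    noise: NoiseConfig
    seed: int | None = None
    panel_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 4:
            raise InvalidInputError("values must be 4-d (gene, cond, time, rep)")
        if v.shape[3] < 1:
            raise InvalidInputError("at least one replicate required")
        if np.any(v < 0):
            raise InvalidInputError("expression values must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[3]

    def replicate_means(self) -> np.ndarray:
        return self.values.mean(axis=3)

    def to_long_frame(self) -> pd.DataFrame:
        g, c, t, r = self.values.shape
        gi, ci, ti, ri = np.unravel_index(np.arange(g * c * t * r), (g, c, t, r))
        return pd.DataFrame(
            {
                "gene": np.asarray(self.gene_labels)[gi],
                "condition": np.asarray(self.condition_signatures)[ci],
                "time_min": np.asarray(self.timepoints)[ti],
                "replicate": ri + 1,
                "value_rpkm": self.values.reshape(-1),
            }
        )


def _shifted_times(tp: np.ndarray, resp_shift, prep_shift) -> np.ndarray:
    """Effective read-out times after response and preparation shifts.

    ``resp_shift``: (..., R) gene/condition/replicate response delay;
    ``prep_shift``: (C, T, R) per-sample preparation shift.  The t = 0
    sample is pinned (unstimulated steady state).  Clamped to [0, 80].
    """
    t_eff = tp[None, None, :, None] - resp_shift[..., None, :] + prep_shift[None, ...]
    t_eff = np.clip(t_eff, 0.0, 80.0)
    t_eff[..., tp == 0.0, :] = 0.0
    return t_eff


def generate_noisy_dataset(
    catalog: GRSCatalog,
    panel: PerturbationPanel,
    n_replicates: int,
    noise: NoiseConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
    normalize: bool = True,
) -> ReplicateDataset:
    """Simulate a replicated noisy dataset for every retained catalog entry.

    Only constant-level panels (high/knockdown/low amplitudes) are
    supported by this generator; those are the panels used for replicated
    designs.  With ``normalize=True`` each gene's values are rescaled by
    its noiseless panel maximum (to 100), the scale on which downstream
    error models operate.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if not panel.is_constant:
        raise ConfigurationError(
            "generate_noisy_dataset requires a constant-level panel; "
            "time-modulated panels are simulation-only"
        )
    noise = noise or NoiseConfig()
    entries = [e for e in catalog.entries if e.status == "retained"]
    if not entries:
        raise InvalidInputError("catalog has no retained entries")
    tp = np.asarray(list(timepoints), dtype=float)
    levels = panel.constant_levels()  # (C, 3)
    C, T, R = levels.shape[0], tp.size, n_replicates

    rng = np.random.default_rng(seed)
    # per-sample preparation shifts, shared by all genes in a sample
    prep = rng.normal(0.0, np.sqrt(noise.prep_time_var), size=(C, T, R)) \
        if noise.prep_time_var > 0 else np.zeros((C, T, R))

    values = np.empty((len(entries), C, T, R))
    for gi, entry in enumerate(entries):
        p = entry.params
        eps_tf = rng.normal(0.0, np.sqrt(noise.tf_amplitude_var), size=(C, R, 3)) \
            if noise.tf_amplitude_var > 0 else np.zeros((C, R, 3))
        tf_eff = np.maximum(levels[:, None, :] * (1.0 + eps_tf), 0.0)
        kin_sd = np.sqrt(noise.kinetic_var)
        kd_eff = np.asarray(p.kd)[None, None, :] * np.exp(
            rng.normal(0.0, kin_sd, size=(C, R, 3)) if kin_sd > 0 else np.zeros((C, R, 3)))
        ksyn_eff = p.ksyn * np.exp(
            rng.normal(0.0, kin_sd, size=(C, R)) if kin_sd > 0 else np.zeros((C, R)))
        kproc_eff = p.kproc * np.exp(
            rng.normal(0.0, kin_sd, size=(C, R)) if kin_sd > 0 else np.zeros((C, R)))
        k0_eff = np.clip(
            p.k0 + (rng.uniform(0.0, noise.k0_uniform_max, size=(C, R))
                    if noise.k0_uniform_max > 0 else 0.0), 0.0, 1.0)
        resp = rng.normal(0.0, np.sqrt(noise.response_time_var), size=(C, R)) \
            if noise.response_time_var > 0 else np.zeros((C, R))

        g = gate_activity(p.logic, tf_eff, kd_eff)  # (C, R)
        f = (1.0 - k0_eff) * g + k0_eff
        ss = ksyn_eff * f / kproc_eff
        basal = ksyn_eff * k0_eff / kproc_eff
        t_eff = _shifted_times(tp, resp[None, :, :], prep)[0]  # (C, T, R)
        y = ss[:, None, :] + (basal - ss)[:, None, :] * np.exp(
            -kproc_eff[:, None, :] * t_eff)
        if noise.measurement_var > 0:
            y = y * (1.0 + rng.normal(0.0, np.sqrt(noise.measurement_var),
                                      size=(C, T, R)))
        values[gi] = np.maximum(y, 0.0)

    if normalize:
        sub = GRSCatalog(tuple(entries), provenance=catalog.provenance)
        clean = panel_response(sub, panel, tp, normalize=False)
        peaks = clean.reshape(len(entries), -1).max(axis=1)
        values *= (100.0 / peaks)[:, None, None, None]

    return ReplicateDataset(
        values=values,
        timepoints=tuple(tp),
        gene_labels=tuple(e.label for e in entries),
        condition_signatures=tuple(c.signature for c in panel.conditions),
        noise=noise,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        panel_name=panel.name,
    )


def empirical_variance(samples: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unbiased (n-1 denominator) per-point variance across samples."""
    s = np.asarray(samples, dtype=float)
    if s.shape[axis] < 2:
        raise InsufficientDataError("need >= 2 samples per point for a variance")
    return s.var(axis=axis, ddof=1)
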