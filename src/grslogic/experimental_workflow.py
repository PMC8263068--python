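"""Application pipeline for measured stimulus-response data.

The workflow mirrors how GRS models are fitted to macrophage immune-
response data: measured TF activities (NFkB, IRF by EMSA/Western; a
MAPK-driven TF proxy inferred from immediate-early genes) are scaled and
cross-normalized; induced genes are selected from nascent-RNA RPKM
tables; every gene is fitted with the 8 logic gates using measured basal
expression as a per-condition offset (k0 = 0); and fitted logics are
called by a likelihood threshold, including the 8 -> 17 logic mapping and
an NFkB-IRF synergy flag.

TF index convention throughout this module: TF1 = NFkB, TF2 = IRF,
TF3 = MAPK-driven TF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
)
from .error_model import ErrorModelParams
from .fitting import FitResult, fit_all_logics
from .grs_core import DEFAULT_TIMEPOINTS, LOGICS

__all__ = [
    "TF_NAMES",
    "SYNERGY_LOGICS",
    "TFActivityPanel",
    "GeneCallTable",
    "scale_tf_activity",
    "normalize_across_conditions",
    "infer_mapk_activity",
    "select_induced_genes",
    "normalize_mapki",
    "fit_with_basal",
    "call_logics",
]

TF_NAMES = ("NFkB", "IRF", "MAPK")

#: 17-logic labels with an NFkB-IRF (TF1-TF2) synergistic component.
SYNERGY_LOGICS = frozenset({
    "TF1.TF2",            # NFkB AND IRF
    "TF1.TF2.TF3",        # NFkB AND IRF AND MAPK
    "TF1.(TF2+TF3)",      # NFkB AND (IRF OR MAPK)
    "TF2.(TF1+TF3)",      # IRF AND (NFkB OR MAPK)
    "TF3+(TF1.TF2)",      # MAPK OR (NFkB AND IRF)
})

#: Denominator floor (RPKM) for fold changes over a zero baseline.
FOLD_CHANGE_FLOOR = 0.1


@dataclass(frozen=True)
class TFActivityPanel:
    """Per-condition scaled TF activity series on a shared time grid."""

    timepoints: tuple[float, ...]
    activities: Mapping[str, np.ndarray] = field(repr=False)  # condition -> (T, 3)

    def levels(self, condition: str) -> np.ndarray:
        return np.asarray(self.activities[condition], dtype=float)


@dataclass(frozen=True)
class GeneCallTable:
    table: pd.DataFrame = field(repr=False)
    nll_threshold: float = 100.0

    def synergy_genes(self) -> list[str]:
        return sorted(self.table.loc[self.table["synergy"], "gene"])


def scale_tf_activity(raw, basal: float, peak: float) -> np.ndarray | float:
    """Linear scaling of band intensities to [0.01, 1].

    scaled = 0.99 * (raw - basal) / (peak - basal) + 0.01, so the basal
    intensity maps to 1% and the peak to 100% activity.  Affine-invariant
    in the raw measurement units.
    """
    if not np.isfinite(basal) or not np.isfinite(peak):
        raise InvalidInputError("basal and peak must be finite")
    if peak <= basal:
        raise DegenerateInputError("peak intensity must exceed basal intensity")
    out = 0.99 * (np.asarray(raw, dtype=float) - basal) / (peak - basal) + 0.01
    if np.ndim(raw) == 0:
        return float(out)
    return out


def normalize_across_conditions(
    scaled: Mapping[str, np.ndarray],
    same_gel_peaks: Mapping[str, float],
    reference: str,
) -> dict[str, np.ndarray]:
    """Cross-condition normalization by same-gel peak ratios.

    Each condition's scaled series is multiplied by
    p_norm = peak(condition) / peak(reference), where both peaks were
    measured on the same gel; the reference (wild type + stimulus)
    peak becomes 1.
    """
    if reference not in same_gel_peaks:
        raise ConfigurationError(f"missing same-gel peak for reference {reference!r}")
    ref_peak = same_gel_peaks[reference]
    if ref_peak <= 0:
        raise InvalidInputError("reference peak intensity must be > 0")
    out = {}
    for cond, series in scaled.items():
        if cond not in same_gel_peaks:
            raise ConfigurationError(f"missing same-gel peak for condition {cond!r}")
        out[cond] = np.asarray(series, dtype=float) * (same_gel_peaks[cond] / ref_peak)
    return out


def infer_mapk_activity(
    ieg_expression: Mapping[str, Mapping[str, np.ndarray]],
    reference: str,
) -> dict[str, np.ndarray]:
    """MAPK-driven TF activity inferred from immediate-early genes.

    ``ieg_expression`` maps gene -> condition -> RPKM series for a set of
    immediate-early genes (e.g. Egr1, Fos, Dusp4) that are neither NFkB
    nor IRF targets.  Each gene is scaled so its basal and peak in the
    reference condition map to 1% and 100%, then genes are averaged per
    condition.  Genes missing a condition are skipped with a warning.
    """
    if not ieg_expression:
        raise ConfigurationError("at least one immediate-early gene is required")
    conditions: set[str] = set()
    for series in ieg_expression.values():
        conditions.update(series)
    scaled: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for gene, series in ieg_expression.items():
        if reference not in series:
            raise ConfigurationError(
                f"gene {gene!r} lacks the reference condition {reference!r}")
        ref = np.asarray(series[reference], dtype=float)
        basal, peak = float(ref[0]), float(ref.max())
        if peak <= basal:
            raise DegenerateInputError(f"gene {gene!r} is not induced in the reference")
        for cond in conditions:
            if cond not in series:
                warnings.warn(f"gene {gene!r} missing condition {cond!r}; "
                              "averaging over remaining genes")
                continue
            scaled[cond].append(scale_tf_activity(series[cond], basal, peak))
    return {c: np.mean(np.stack(v), axis=0) for c, v in scaled.items() if v}


def select_induced_genes(
    expression: pd.DataFrame,
    significance: Mapping[str, float] | pd.DataFrame,
    peak_min_rpkm: float = 3.0,
    fold_min: float = 10.0,
    p_max: float = 0.01,
    early_fold_min: float = 5.0,
    early_time: float = 15.0,
) -> pd.DataFrame:
    """Select induced genes from a long expression table.

    A gene is induced if (peak RPKM > 3 at any timepoint AND > 10-fold
    over t = 0 at any timepoint AND p < 0.01) OR it shows > 5-fold
    induction at 15 min.  The returned frame records which rule fired.
    Fold changes over a zero baseline use a 0.1 RPKM denominator floor.
    ``significance`` maps gene -> p-value (differential testing is an
    external input).
    """
    required = {"gene", "time_min", "value_rpkm"}
    if not required.issubset(expression.columns):
        raise InvalidInputError(f"expression table needs columns {sorted(required)}")
    if isinstance(significance, pd.DataFrame):
        significance = dict(zip(significance["gene"], significance["p_value"]))
    rows = []
    for gene, sub in expression.groupby("gene"):
        prof = sub.groupby("time_min")["value_rpkm"].mean()
        if 0.0 not in prof.index:
            raise InvalidInputError(f"gene {gene!r} lacks a t=0 sample")
        base = max(prof.loc[0.0], FOLD_CHANGE_FLOOR)
        peak = float(prof.max())
        fold = float(prof.max() / base)
        p = float(significance.get(gene, 1.0))
        main_rule = (peak > peak_min_rpkm) and (fold > fold_min) and (p < p_max)
        early = float(prof.loc[early_time] / base) if early_time in prof.index else 0.0
        early_rule = early > early_fold_min
        if main_rule or early_rule:
            rows.append({"gene": gene, "peak_rpkm": peak, "max_fold": fold,
                         "p_value": p,
                         "rule": "peak_fold_p" if main_rule else "early_fold"})
    return pd.DataFrame(rows, columns=["gene", "peak_rpkm", "max_fold",
                                       "p_value", "rule"])


def normalize_mapki(
    inhibitor: np.ndarray, control: np.ndarray, wt: np.ndarray,
    floor: float = FOLD_CHANGE_FLOOR,
) -> np.ndarray:
    """Adjust an inhibitor series for vehicle effects.

    Each timepoint is multiplied by WT(t)/control(t), making the
    MAPK-inhibited condition comparable to the other conditions; zero
    control values are floored with a warning.
    """
    inh = np.asarray(inhibitor, dtype=float)
    ctl = np.asarray(control, dtype=float)
    wtv = np.asarray(wt, dtype=float)
    if inh.shape != ctl.shape or inh.shape != wtv.shape:
        raise InvalidInputError("inhibitor, control and WT series must share a grid")
    if np.any(ctl <= 0):
        warnings.warn("control series has non-positive values; flooring")
        ctl = np.maximum(ctl, floor)
    return inh * (wtv / ctl)


def fit_with_basal(
    y_obs: np.ndarray,
    levels: np.ndarray,
    error_params: ErrorModelParams,
    basal: np.ndarray,
    slopes: np.ndarray | None = None,
    gene: str = "gene",
    timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
    n_starts: int = 300,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> FitResult:
    """Fit the 8 gates with measured basal expression as a fixed offset.

    The model's own basal activity is disabled (k0 = 0) and the measured
    unstimulated expression of each condition is added to the raw model
    output, so fitted curves reproduce the measured basal at t = 0.
    """
    basal = np.asarray(basal, dtype=float)
    if np.any(basal < 0):
        raise InvalidInputError("basal expression must be >= 0")
    if basal.shape[0] != np.asarray(levels).shape[0]:
        raise InvalidInputError("one basal value per condition is required")
    return fit_all_logics(
        y_obs, levels, error_params, slopes=slopes, gene=gene,
        n_starts=n_starts, seed=seed, fit_k0=False, basal=basal,
        timepoints=timepoints, **kwargs,
    )


def call_logics(
    fit_results: Sequence[FitResult],
    nll_threshold: float = 100.0,
) -> GeneCallTable:
    """Accept fitted logics below an NLL threshold and classify genes.

    For each gene, every one of the 8 gates whose NLL is below the
    threshold is accepted (after 8 -> 17 mapping of its fitted Kds); a
    gene is single-TF iff every accepted logic maps to a single-TF label,
    synergy-flagged iff any accepted logic is in the NFkB-IRF synergy
    list, and "unexplained" when no logic is accepted.
    """
    from .fitting import map_to_17

    if nll_threshold is None or not np.isfinite(nll_threshold):
        raise ConfigurationError("nll_threshold must be finite")
    rows = []
    for res in fit_results:
        accepted = []
        for logic in LOGICS:
            if res.nll_per_logic[logic] < nll_threshold:
                label, _ = map_to_17(logic, res.params_per_logic[logic].kd)
                accepted.append(label)
        accepted_set = sorted(set(a for a in accepted if a != "basal"))
        single_only = bool(accepted_set) and all(
            a.count("TF") == 1 for a in accepted_set)
        rows.append({
            "gene": res.gene,
            "best_logic": res.selected_logic,
            "best_label": res.logic17_label,
            "best_nll": res.selected_nll,
            "accepted_logics": ";".join(accepted_set),
            "n_accepted": len(accepted_set),
            "unexplained": not accepted_set,
            "single_tf_only": single_only,
            "synergy": any(a in SYNERGY_LOGICS for a in accepted_set),
        })
    return GeneCallTable(pd.DataFrame(rows), nll_threshold=nll_threshold)
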