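"""GRS catalogs, perturbation panels, and distinguishability analysis.

The representative catalog crosses the 8 triple logic gates with three
regulation strengths per TF (Strong/Medium/Weak = Kd 0.1/1/10), giving 216
configurations.  Two filters reduce these to the 93 unique, potentially
identifiable GRSs:

* activatability -- configurations whose full-stimulation output stays at
  or below a threshold (poor activation, typically a Weak TF inside an AND
  gate) are flagged; the threshold reported for downstream use is the
  maximum output over this flagged set (1.66 RPKM for Table-1 kinetics);
* redundancy -- configurations that are logically equivalent to a simpler
  single- or dual-TF gate (a Weak strength acts as a null regulation) are
  collapsed onto one canonical representative per equivalence class.

Panels are named sets of per-TF waveform assignments; distinguishability
is assessed by squared-Euclidean distances between normalized simulated
responses, single-linkage hierarchical clustering, and cluster counts as a
function of the tree-cut ("separation") threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, InvalidInputError
from .grs_core import (
    DEFAULT_TIMEPOINTS,
    GRSParameters,
    LOGICS,
    TFTrajectory,
    build_waveform,
    gate_activity,
    promoter_activity,
)

__all__ = [
    "STRENGTH_KD",
    "CatalogEntry",
    "GRSCatalog",
    "PerturbationCondition",
    "PerturbationPanel",
    "ClusterTree",
    "enumerate_representative_catalog",
    "filter_activatable",
    "deduplicate",
    "reduce_effective_logic",
    "build_panel",
    "conditions_from_signatures",
    "panel_response",
    "distance_matrix",
    "cluster_tree",
    "count_clusters",
    "sample_random_catalog",
    "peak_output",
]

#: Regulation strengths in TF-activity units.
STRENGTH_KD = {"S": 0.1, "M": 1.0, "W": 10.0}

#: Poor-activation cutoff on full-stimulation *fractional* gate activity.
#: A configuration that cannot drive at least one sixth of maximal promoter
#: activity with all three TFs fully active is considered not efficiently
#: activatable.  For Table-1 kinetics (ksyn = 1 RPKM/min, kproc = 0.1/min)
#: the largest output in the flagged set evaluates to 1.66 RPKM.
ACTIVATABLE_GATE_FRACTION = 1.0 / 6.0


@dataclass(frozen=True)
class CatalogEntry:
    label: str
    params: GRSParameters
    strengths: tuple[str, str, str] | None = None
    status: str = "retained"  # retained | poorly_activated | redundant
    effective_logic: str | None = None
    effective_strengths: tuple[str, ...] | None = None
    representative: str | None = None


@dataclass(frozen=True)
class GRSCatalog:
    """An ordered, labelled collection of GRS configurations."""

    entries: tuple[CatalogEntry, ...]
    provenance: str = "representative"
    activatability_threshold: float | None = None

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(labels) != len(set(labels)):
            raise InvalidInputError("catalog labels must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def retained(self) -> "GRSCatalog":
        return replace(
            self, entries=tuple(e for e in self.entries if e.status == "retained")
        )

    def with_status(self, status: str) -> tuple[CatalogEntry, ...]:
        return tuple(e for e in self.entries if e.status == status)

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def params_arrays(self):
        """Per-logic grouping of kinetic parameter arrays (for batch work)."""
        out = {}
        for logic in LOGICS:
            idx = [i for i, e in enumerate(self.entries) if e.params.logic == logic]
            if not idx:
                continue
            kd = np.array([self.entries[i].params.kd for i in idx])
            ksyn = np.array([self.entries[i].params.ksyn for i in idx])
            kproc = np.array([self.entries[i].params.kproc for i in idx])
            k0 = np.array([self.entries[i].params.k0 for i in idx])
            out[logic] = (np.asarray(idx), kd, ksyn, kproc, k0)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "label": e.label,
                    "logic": e.params.logic,
                    "kd1": e.params.kd[0],
                    "kd2": e.params.kd[1],
                    "kd3": e.params.kd[2],
                    "ksyn": e.params.ksyn,
                    "kproc": e.params.kproc,
                    "k0": e.params.k0,
                    "status": e.status,
                    "effective_logic": e.effective_logic or "",
                    "representative": e.representative or "",
                }
            )
        return pd.DataFrame(rows)


def enumerate_representative_catalog() -> GRSCatalog:
    """All 8 logics x 27 strength triples = 216 representative GRSs."""
    entries = []
    for logic in LOGICS:
        for strengths in itertools.product("SMW", repeat=3):
            kd = tuple(STRENGTH_KD[s] for s in strengths)
            label = f"{logic}:{','.join(strengths)}"
            entries.append(
                CatalogEntry(
                    label=label,
                    params=GRSParameters(logic=logic, kd=kd, ksyn=1.0, kproc=0.1, k0=0.0),
                    strengths=tuple(strengths),
                )
            )
    return GRSCatalog(tuple(entries), provenance="representative")


def peak_output(params: GRSParameters, t_max: float = 60.0) -> float:
    """Peak nascent RNA on [0, t_max] under sustained full stimulation.

    For constant full activation the response rises monotonically from the
    basal steady state, so the peak is the value at ``t_max``.
    """
    g = gate_activity(params.logic, (1.0, 1.0, 1.0), params.kd)
    f = promoter_activity(g, params.k0)
    ss = params.ksyn * f / params.kproc
    basal = params.basal_steady_state
    return float(ss + (basal - ss) * np.exp(-params.kproc * t_max))


def filter_activatable(
    catalog: GRSCatalog, threshold_rpkm: float | None = None
) -> GRSCatalog:
    """Flag poorly-activated entries and record the activatability threshold.

    With an explicit ``threshold_rpkm`` (e.g. the 1.66 RPKM used for random
    catalogs), an entry is poorly activated iff its peak output under full
    stimulation is <= the threshold.  Without one, the filter uses the
    fractional-activity rule (full-stimulation gate activity <= 1/6 of the
    entry's own maximal output) and then reports the threshold as the
    maximum peak output over the flagged set.
    """
    if threshold_rpkm is not None and threshold_rpkm < 0:
        raise ConfigurationError("activatability threshold must be >= 0")
    peaks = np.array([peak_output(e.params) for e in catalog.entries])
    if threshold_rpkm is None:
        # entry's own full-activity reference output (f = 1)
        ref = np.array(
            [
                peak_output(replace_params_full(e.params))
                for e in catalog.entries
            ]
        )
        flagged = peaks <= ACTIVATABLE_GATE_FRACTION * ref + 1e-12
        threshold = float(peaks[flagged].max()) if flagged.any() else 0.0
    else:
        flagged = peaks <= threshold_rpkm
        threshold = float(threshold_rpkm)
    entries = tuple(
        replace(e, status="poorly_activated") if fl else e
        for e, fl in zip(catalog.entries, flagged)
    )
    return replace(catalog, entries=entries, activatability_threshold=threshold)


def replace_params_full(params: GRSParameters) -> GRSParameters:
    """Same kinetics with saturating regulation (tiny Kd): output ceiling."""
    return GRSParameters(logic=params.logic, kd=(1e-9, 1e-9, 1e-9),
                         ksyn=params.ksyn, kproc=params.kproc, k0=params.k0)


# ---------------------------------------------------------------------------
# Logical-equivalence reduction (Weak strength acts as a null regulation)
# ---------------------------------------------------------------------------


def _dual_label(i: int, j: int, op: str) -> str:
    a, b = sorted((i, j))
    sep = "." if op == "AND" else "+"
    return f"TF{a}{sep}TF{b}"


def reduce_effective_logic(
    logic: str, strengths: Sequence[str]
) -> tuple[str | None, tuple[str, ...]]:
    """Reduce a triple gate with Weak (null-like) strengths to its effective logic.

    Returns the effective logic label among the 17 single/dual/triple
    logics together with the strengths of the surviving TFs, or ``(None,
    ())`` when the gate reduces to a constant (no effective regulation).
    A Weak TF drops out of an OR and kills an AND it is required in.
    """
    s = tuple(strengths)
    null = [s_i == "W" for s_i in s]
    idx = LOGICS.index(logic)
    if logic == "TF1.TF2.TF3":
        if any(null):
            return None, ()
        return logic, s
    if 1 <= idx <= 3:  # TFi AND (TFj OR TFk)
        i = idx - 1
        j, k = [x for x in range(3) if x != i]
        if null[i] or (null[j] and null[k]):
            return None, ()
        if null[j]:
            return _dual_label(i + 1, k + 1, "AND"), (s[min(i, k)], s[max(i, k)])
        if null[k]:
            return _dual_label(i + 1, j + 1, "AND"), (s[min(i, j)], s[max(i, j)])
        return logic, s
    if 4 <= idx <= 6:  # TFi OR (TFj AND TFk)
        i = idx - 4
        j, k = [x for x in range(3) if x != i]
        if null[j] or null[k]:
            if null[i]:
                return None, ()
            return f"TF{i + 1}", (s[i],)
        if null[i]:
            return _dual_label(j + 1, k + 1, "AND"), (s[min(j, k)], s[max(j, k)])
        return logic, s
    # OR-OR
    alive = [x for x in range(3) if not null[x]]
    if not alive:
        return None, ()
    if len(alive) == 1:
        return f"TF{alive[0] + 1}", (s[alive[0]],)
    if len(alive) == 2:
        a, b = alive
        return _dual_label(a + 1, b + 1, "OR"), (s[a], s[b])
    return logic, s


#: Numeric Kd used for a null regulation strength in canonical reduced
#: gates (Kd >> 1; the Hill term is ~1e-6 at full activity).
NULL_KD = 1e6


def _canonical_reduced_entry(eff_logic: str, eff_s: tuple[str, ...],
                             template: GRSParameters) -> CatalogEntry:
    """The ideal single/dual gate: host triple logic with exact null Kds."""
    i_list = sorted(int(c) for c in eff_logic if c.isdigit())
    kd = [NULL_KD] * 3
    strengths: list[str] = ["-"] * 3
    for tf, s in zip(i_list, eff_s):
        kd[tf - 1] = STRENGTH_KD[s]
        strengths[tf - 1] = s
    if len(i_list) == 1:
        (i,) = i_list
        host = LOGICS[3 + i]  # TFi OR (TFj AND TFk): exactly h_i with nulls
    elif "." in eff_logic:
        i, j = i_list
        k = 6 - i - j
        host = f"TF{i}.(TF{min(j, k)}+TF{max(j, k)})"  # exactly h_i*h_j
    else:
        host = "TF1+TF2+TF3"  # dual OR: exactly 1-(1-h_i)(1-h_j)
    label = f"{eff_logic}:{','.join(eff_s)}"
    return CatalogEntry(
        label=label,
        params=GRSParameters(logic=host, kd=tuple(kd), ksyn=template.ksyn,
                             kproc=template.kproc, k0=template.k0),
        strengths=tuple(strengths),
        status="retained",
        effective_logic=eff_logic,
        effective_strengths=eff_s,
        representative=label,
    )


def deduplicate(catalog: GRSCatalog) -> GRSCatalog:
    """Collapse logically equivalent activatable entries onto one representative.

    Activatable entries are grouped by their effective logic (Weak-as-null
    reduction) and the strengths of the surviving TFs.  Triple-logic
    classes are singletons and stay as they are.  Single/dual classes are
    represented canonically by the ideal reduced gate -- a host triple
    logic with exact null strengths (Kd = 1e6) for the dropped TFs, the
    Kd >> 1 representation of single/dual logics -- replacing the Weak
    approximations, which are flagged redundant.  An activatable entry
    whose effective logic is empty (the all-Weak OR gate) is likewise
    redundant.  Idempotent.
    """
    groups: dict[tuple, list[int]] = {}
    entries = list(catalog.entries)
    for i, e in enumerate(entries):
        if e.status == "poorly_activated":
            continue
        if e.strengths is None:
            raise InvalidInputError("deduplicate requires strength-labelled entries")
        if "-" in e.strengths:  # already a canonical reduced gate
            groups.setdefault((e.effective_logic, e.effective_strengths), []).append(i)
            continue
        eff_logic, eff_s = reduce_effective_logic(e.params.logic, e.strengths)
        entries[i] = replace(e, effective_logic=eff_logic, effective_strengths=eff_s,
                             status="retained", representative=None)
        if eff_logic is None:
            entries[i] = replace(entries[i], status="redundant")
            continue
        groups.setdefault((eff_logic, eff_s), []).append(i)
    for key, members in groups.items():
        eff_logic, eff_s = key
        if len(eff_s) == 3:
            # singleton triple class: the entry represents itself
            (i,) = members
            entries[i] = replace(entries[i], representative=entries[i].label)
            continue
        members.sort(key=lambda i: (LOGICS.index(entries[i].params.logic),
                                    entries[i].label))
        canon = _canonical_reduced_entry(eff_logic, eff_s, entries[members[0]].params)
        lead = next((i for i in members if entries[i].label == canon.label),
                    members[0])
        entries[lead] = canon  # canonical gate takes (or keeps) the lead slot
        for i in members:
            if i != lead:
                entries[i] = replace(entries[i], status="redundant",
                                     representative=canon.label)
    return replace(catalog, entries=tuple(entries))


# ---------------------------------------------------------------------------
# Perturbation panels
# ---------------------------------------------------------------------------

_PANEL_KINDS = {
    "amplitude26": "amplitude",
    "gradient26": "gradient",
    "delayed26": "delayed",
    "transient26": "transient",
}

_LEVEL_WAVEFORM = {"H": ("high", None), "M": ("amplitude", 0.5), "L": ("low", None)}


@dataclass(frozen=True)
class PerturbationCondition:
    signature: str
    waveforms: tuple[TFTrajectory, TFTrajectory, TFTrajectory]

    @property
    def is_constant(self) -> bool:
        return all(w.kind in ("high", "low", "amplitude") for w in self.waveforms)

    def constant_levels(self) -> tuple[float, float, float]:
        if not self.is_constant:
            raise InvalidInputError("condition has time-varying waveforms")
        return tuple(w.level for w in self.waveforms)


@dataclass(frozen=True)
class PerturbationPanel:
    name: str
    conditions: tuple[PerturbationCondition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigurationError("a panel needs at least one condition")
        sigs = [c.signature for c in self.conditions]
        if len(sigs) != len(set(sigs)):
            raise ConfigurationError("duplicated condition signatures in panel")

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def is_constant(self) -> bool:
        return all(c.is_constant for c in self.conditions)

    def constant_levels(self) -> np.ndarray:
        return np.array([c.constant_levels() for c in self.conditions])


def conditions_from_signatures(
    signatures: Iterable[str], medium: float = 0.5
) -> tuple[PerturbationCondition, ...]:
    """Build constant-level conditions from H/M/L letter signatures."""
    conds = []
    levels = {"H": 1.0, "M": medium, "L": 0.0}
    for sig in signatures:
        if len(sig) != 3 or any(c not in levels for c in sig):
            raise ConfigurationError(f"bad condition signature {sig!r}")
        waves = tuple(
            build_waveform("high") if c == "H"
            else build_waveform("low") if c == "L"
            else build_waveform("amplitude", medium)
            for c in sig
        )
        conds.append(PerturbationCondition(sig, waves))
    return tuple(conds)


def build_panel(name: str, conditions: Iterable[str] | None = None) -> PerturbationPanel:
    """Construct a named perturbation panel.

    ``simple7``: all high/low combinations minus all-low (7 conditions).
    ``amplitude26``/``gradient26``/``delayed26``/``transient26``: per-TF
    assignment over {high, modified, low} minus all-low (26 conditions),
    where "modified" is the panel's waveform kind.  ``custom`` takes an
    explicit list of H/M/L signatures (M = constant 0.5 knockdown level).
    """
    if name == "custom":
        if conditions is None:
            raise ConfigurationError("custom panel requires explicit conditions")
        return PerturbationPanel("custom", conditions_from_signatures(conditions))
    if name == "simple7":
        sigs = ["".join(c) for c in itertools.product("HL", repeat=3) if set(c) != {"L"}]
        return PerturbationPanel(name, conditions_from_signatures(sigs))
    if name in _PANEL_KINDS:
        mod_kind = _PANEL_KINDS[name]
        conds = []
        for letters in itertools.product("HML", repeat=3):
            if set(letters) == {"L"}:
                continue
            waves = tuple(
                build_waveform("high") if c == "H"
                else build_waveform("low") if c == "L"
                else build_waveform(mod_kind)
                for c in letters
            )
            conds.append(PerturbationCondition("".join(letters), waves))
        return PerturbationPanel(name, tuple(conds))
    raise ConfigurationError(f"unknown panel {name!r}")


# ---------------------------------------------------------------------------
# Batched simulation of a catalog over a panel
# ---------------------------------------------------------------------------


def _condition_grid(cond: PerturbationCondition, timepoints: np.ndarray,
                    dt: float = 0.125) -> np.ndarray:
    """Integration grid for one condition, containing all sample times."""
    t_end = max(float(timepoints.max(initial=0.0)), 60.0)
    if any(w.kind == "gradient" for w in cond.waveforms):
        grid = np.arange(0.0, t_end + dt / 2, dt)
    else:
        breaks = {0.0, t_end}
        for w in cond.waveforms:
            if w.segments:
                for t0, t1, _ in w.segments:
                    breaks.update((t0, t1))
        grid = np.asarray(sorted(b for b in breaks if 0.0 <= b <= t_end))
    return np.unique(np.concatenate([grid, timepoints]))


def panel_response(
    catalog: GRSCatalog,
    panel: PerturbationPanel,
    timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
    normalize: bool = True,
) -> np.ndarray:
    """Simulate every catalog entry under every panel condition.

    Returns an array of shape (n_entries, n_conditions, n_timepoints).
    With ``normalize=True`` each entry's response is rescaled so that its
    maximum across the whole panel equals 100 (the ksyn-invariant view).
    """
    tp = np.asarray(list(timepoints), dtype=float)
    n = len(catalog.entries)
    out = np.empty((n, len(panel.conditions), tp.size))
    by_logic = catalog.params_arrays()
    for ci, cond in enumerate(panel.conditions):
        grid = _condition_grid(cond, tp)
        mids = 0.5 * (grid[:-1] + grid[1:])
        tf_mid = np.stack([np.asarray(w(mids), dtype=float) for w in cond.waveforms],
                          axis=-1)  # (T-1, 3)
        sample_idx = np.searchsorted(grid, tp)
        for logic, (idx, kd, ksyn, kproc, k0) in by_logic.items():
            g = gate_activity(logic, tf_mid[None, :, :], kd[:, None, :])  # (m, T-1)
            f = (1.0 - k0[:, None]) * g + k0[:, None]
            rna = ksyn * k0 / kproc  # basal steady state
            traj = np.empty((len(idx), grid.size))
            traj[:, 0] = rna
            dts = np.diff(grid)
            kp = kproc[:, None]
            ss = ksyn[:, None] * f / kp
            decay = np.exp(-kp * dts[None, :])
            cur = traj[:, 0].copy()
            for s in range(dts.size):
                cur = ss[:, s] + (cur - ss[:, s]) * decay[:, s]
                traj[:, s + 1] = cur
            out[idx[:, None], ci, np.arange(tp.size)[None, :]] = traj[:, sample_idx]
    if normalize:
        peaks = out.reshape(n, -1).max(axis=1)
        if np.any(peaks <= 0):
            bad = [catalog.entries[i].label for i in np.nonzero(peaks <= 0)[0]]
            raise InvalidInputError(f"all-zero responses cannot be normalized: {bad[:3]}")
        out = out * (100.0 / peaks)[:, None, None]
    return out


# ---------------------------------------------------------------------------
# Distance matrix and hierarchical clustering
# ---------------------------------------------------------------------------


def distance_matrix(responses: np.ndarray) -> np.ndarray:
    """Pairwise squared-Euclidean distances over all conditions and timepoints.

    d(i, j) = sum_p sum_t (ge_i,p(t) - ge_j,p(t))^2
    """
    resp = np.asarray(responses, dtype=float)
    if resp.ndim < 2:
        raise InvalidInputError("responses must be (n, conditions, timepoints)")
    flat = resp.reshape(resp.shape[0], -1)
    sq = np.sum(flat**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


@dataclass(frozen=True)
class ClusterTree:
    distances: np.ndarray = field(repr=False)
    method: str
    merges: np.ndarray = field(repr=False)  # scipy linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2]


def cluster_tree(distances: np.ndarray, linkage: str = "single") -> ClusterTree:
    """Agglomerative clustering of a symmetric squared-distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=1e-8, atol=1e-8):
        raise InvalidInputError("distance matrix must be symmetric")
    if linkage not in ("single", "average", "complete"):
        raise ConfigurationError(f"unsupported linkage {linkage!r}")
    condensed = squareform(d, checks=False)
    merges = scipy_linkage(condensed, method=linkage)
    return ClusterTree(distances=d, method=linkage, merges=merges)


def count_clusters(tree: ClusterTree, separation_threshold: float) -> int:
    """Number of clusters when the tree is cut at the given height."""
    labels = fcluster(tree.merges, t=separation_threshold, criterion="distance")
    return int(labels.max())


# ---------------------------------------------------------------------------
# Random parameter sampling
# ---------------------------------------------------------------------------

#: Sampling ranges for the random catalog (Kd and kproc log-uniform,
#: k0 uniform-linear because its range includes 0; ksyn fixed at 1 since a
#: sampled ksyn is cancelled by normalization).
RANDOM_RANGES = {"kd": (0.01, 100.0), "kproc": (0.01, 10.0), "k0": (0.0, 1.0)}

#: Activatability cutoff (RPKM) for randomly sampled GRSs: the maximum
#: output among the representative catalog's poorly-activated set.
RANDOM_ACTIVATABILITY_THRESHOLD = 1.66


def sample_random_catalog(
    n_per_logic: int,
    ranges: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
    threshold_rpkm: float | None = RANDOM_ACTIVATABILITY_THRESHOLD,
) -> GRSCatalog:
    """Sample ``n_per_logic`` parameter sets per logic and flag activatability."""
    if n_per_logic <= 0:
        raise ConfigurationError("n_per_logic must be positive")
    rng = np.random.default_rng(seed)
    r = dict(RANDOM_RANGES)
    if ranges:
        r.update(ranges)
    for key in ("kd", "kproc"):
        lo, hi = r[key]
        if not (0 < lo < hi):
            raise ConfigurationError(f"invalid {key} range {r[key]}")
    entries = []
    for logic in LOGICS:
        kd = 10 ** rng.uniform(np.log10(r["kd"][0]), np.log10(r["kd"][1]),
                               size=(n_per_logic, 3))
        kproc = 10 ** rng.uniform(np.log10(r["kproc"][0]), np.log10(r["kproc"][1]),
                                  size=n_per_logic)
        k0 = rng.uniform(r["k0"][0], r["k0"][1], size=n_per_logic)
        for i in range(n_per_logic):
            entries.append(
                CatalogEntry(
                    label=f"{logic}#{i:04d}",
                    params=GRSParameters(logic=logic, kd=tuple(kd[i]), ksyn=1.0,
                                         kproc=float(kproc[i]), k0=float(k0[i])),
                )
            )
    cat = GRSCatalog(tuple(entries), provenance="sampled")
    if threshold_rpkm is not None:
        cat = filter_activatable(cat, threshold_rpkm=threshold_rpkm)
    return cat
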