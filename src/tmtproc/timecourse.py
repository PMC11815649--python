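"""Time-course analysis: razor assignment, anchor normalization, protein
roll-up, hierarchical k-means clustering and fold-change summaries.

Peptide-level quantification drifts with acquisition efficiency between
channels; scaling each stage so that the pooled signal of anchor proteins
(mitochondrial proteins in the embryo datasets, whose abundance is treated
as constant across development) is level removes that drift.  Peptides are
rolled up to proteins by a median of mean-scaled profiles, and protein
trajectories are clustered with hierarchical k-means: Ward-linkage
centroids initialize standard Lloyd iterations, making the result
deterministic for a fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

_META_COLUMNS = ("protein", "is_anchor")


@dataclass
class QuantMatrix:
    """Rows = peptides (or proteins), columns = ordered stages.

    ``meta`` carries per-row metadata (protein id, anchor flag) aligned on
    the same index.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if len(self.meta) and not self.meta.index.equals(self.values.index):
            raise ValueError("meta must be aligned with values")

    @property
    def stages(self) -> list:
        return list(self.values.columns)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.meta.copy())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, index_col: str = "peptide") -> "QuantMatrix":
        df = df.set_index(index_col)
        meta_cols = [c for c in _META_COLUMNS if c in df.columns]
        return cls(df.drop(columns=meta_cols), df[meta_cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.meta, self.values], axis=1).reset_index()


# ---------------------------------------------------------------------------
# razor assignment
# ---------------------------------------------------------------------------

def assign_peptides_to_proteins(peptide_candidates: dict) -> dict:
    """Razor rule: map each peptide to one protein.

    ``peptide_candidates`` maps peptide -> iterable of candidate protein ids.
    Unique peptides are assigned directly; shared peptides go to the
    candidate with the most unique peptides, ties broken lexicographically.
    """
    unique_counts: dict = {}
    for pep, cands in peptide_candidates.items():
        cands = list(cands)
        if not cands:
            raise ValueError(f"peptide {pep!r} has no candidate proteins")
        if len(cands) == 1:
            unique_counts[cands[0]] = unique_counts.get(cands[0], 0) + 1
    assignment = {}
    for pep, cands in peptide_candidates.items():
        cands = sorted(set(cands))
        if len(cands) == 1:
            assignment[pep] = cands[0]
            continue
        best = max(cands, key=lambda p: (unique_counts.get(p, 0), ))
        top = [p for p in cands if unique_counts.get(p, 0) == unique_counts.get(best, 0)]
        if len(top) > 1:
            log.info("peptide %s: razor tie between %s; lexicographic pick", pep, top)
        assignment[pep] = min(top)
    return assignment


# ---------------------------------------------------------------------------
# normalization and roll-up
# ---------------------------------------------------------------------------

def normalize_to_anchor(matrix: QuantMatrix, anchor_ids=None,
                        stat: str = "sum") -> QuantMatrix:
    """Scale each stage so the pooled anchor signal is constant.

    Anchor rows are those flagged ``is_anchor`` in the metadata or whose
    protein is in ``anchor_ids``.  The common anchor level is set to the
    pre-normalization mean across stages, so total anchor signal is
    preserved.  Idempotent.
    """
    meta = matrix.meta
    mask = pd.Series(False, index=matrix.values.index)
    if "is_anchor" in meta.columns:
        mask |= meta["is_anchor"].astype(bool)
    if anchor_ids is not None and "protein" in meta.columns:
        mask |= meta["protein"].isin(set(anchor_ids))
    if not mask.any():
        raise ValueError("no anchor peptides found")
    agg = getattr(matrix.values.loc[mask], stat)(axis=0)
    if (agg <= 0).any():
        bad = list(agg.index[agg <= 0])
        raise ValueError(f"stage(s) with zero anchor signal: {bad}")
    factors = agg.mean() / agg
    return QuantMatrix(matrix.values * factors, meta.copy())


def rollup_proteins(matrix: QuantMatrix, assignment: dict | None = None) -> QuantMatrix:
    """Aggregate peptide rows into protein rows.

    Each peptide profile is scaled to its own mean (the median-corrected
    step), the per-stage median across a protein's peptides is taken, and
    the result is rescaled so the protein row carries its peptides' summed
    signal.  Proteins with no quantified peptide are dropped with a log
    entry.
    """
    proteins = (pd.Series(assignment) if assignment is not None
                else matrix.meta["protein"]).reindex(matrix.values.index)
    rows, index, meta_rows = [], [], []
    for protein, group in matrix.values.groupby(proteins, sort=True):
        totals = group.sum(axis=1)
        quantified = group.loc[totals > 0]
        if quantified.empty:
            log.info("protein %s has no quantified peptides; dropped", protein)
            continue
        scaled = quantified.div(quantified.mean(axis=1), axis=0)
        shape = scaled.median(axis=0)
        profile = shape * (quantified.to_numpy().sum() / shape.sum())
        rows.append(profile)
        index.append(protein)
        is_anchor = False
        if "is_anchor" in matrix.meta.columns:
            is_anchor = bool(matrix.meta.loc[group.index, "is_anchor"].any())
        meta_rows.append({"protein": protein, "is_anchor": is_anchor,
                          "n_peptides": len(quantified)})
    values = pd.DataFrame(rows, index=index, columns=matrix.values.columns)
    meta = pd.DataFrame(meta_rows, index=index)
    return QuantMatrix(values, meta)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _row_profiles(x: np.ndarray) -> np.ndarray:
    sums = x.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("every row must have positive total signal")
    return x / sums


def hkmeans_cluster(matrix: np.ndarray, k: int, seed: int = 0,
                    normalize: bool = True, max_iter: int = 300):
    """Hierarchical k-means: Ward-cut centroids seed Lloyd iterations.

    Rows are first normalized to fractional profiles so clusters reflect
    trajectory shape rather than abundance.  Deterministic given input
    order.  Returns ``(labels, centroids)``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not 1 <= k <= len(x):
        raise ValueError(f"k must be in 1..{len(x)}")
    if normalize:
        x = _row_profiles(x)
    if k == 1:
        return np.zeros(len(x), dtype=int), x.mean(axis=0, keepdims=True)
    link = _hier.linkage(x, method="ward")
    init_labels = _hier.fcluster(link, t=k, criterion="maxclust") - 1
    centroids = np.vstack([x[init_labels == c].mean(axis=0) for c in range(k)])
    km = KMeans(n_clusters=k, init=centroids, n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(x)
    return labels, km.cluster_centers_


def two_pass_cluster(matrix: np.ndarray, k_first: int, k_second: int,
                     isolate: int | None = None, seed: int = 0):
    """Two-pass schedule: cluster at ``k_first``, isolate one cluster,
    recluster the remainder at ``k_second``.

    ``isolate`` picks the cluster to set aside (default: the largest).
    Returns labels where 0 is the isolated cluster and 1..k_second the
    reclustered remainder.
    """
    x = np.asarray(matrix, dtype=float)
    first, _ = hkmeans_cluster(x, k_first, seed=seed)
    if isolate is None:
        isolate = int(np.bincount(first).argmax())
    keep = first != isolate
    labels = np.zeros(len(x), dtype=int)
    if keep.sum() >= k_second:
        second, _ = hkmeans_cluster(x[keep], k_second, seed=seed)
        labels[keep] = second + 1
    elif keep.any():
        labels[keep] = 1
    return labels


# ---------------------------------------------------------------------------
# fold changes and orthogroups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldChangeSummary:
    log2_first_last: np.ndarray
    fraction_decreasing: float
    fraction_increasing: float
    n_floored: int = 0

    @property
    def fraction_within(self) -> float:
        return 1.0 - self.fraction_decreasing - self.fraction_increasing


def fold_change_summary(matrix: np.ndarray, threshold_fold: float = 2.0) -> FoldChangeSummary:
    """Per-protein log2(first/last) ratios and the fractions changing
    beyond ``threshold_fold``.

    A positive log2 ratio means the protein decreased across the course.
    Zeros are floored at half the smallest positive value in the matrix.
    """
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must be > 1")
    x = np.asarray(matrix, dtype=float)
    first, last = x[:, 0].copy(), x[:, -1].copy()
    positive = x[x > 0]
    floor = 0.5 * positive.min() if len(positive) else 1.0
    n_floored = int((first <= 0).sum() + (last <= 0).sum())
    first[first <= 0] = floor
    last[last <= 0] = floor
    ratios = np.log2(first / last)
    cut = np.log2(threshold_fold)
    return FoldChangeSummary(
        log2_first_last=ratios,
        fraction_decreasing=float((ratios > cut).mean()),
        fraction_increasing=float((ratios < -cut).mean()),
        n_floored=n_floored,
    )


def orthogroup_representatives(orthogroups: pd.DataFrame,
                               quantified_peptide_counts: dict) -> dict:
    """One representative protein per (orthogroup, organism).

    ``orthogroups`` needs columns orthogroup_id, organism, protein_id.  When
    several proteins of an orthogroup are detected in an organism, the one
    with the most quantified peptides wins; ties break lexicographically.
    Proteins absent from the quantification results are ignored.
    """
    required = {"orthogroup_id", "organism", "protein_id"}
    if missing := required - set(orthogroups.columns):
        raise ValueError(f"orthogroup table missing column(s): {sorted(missing)}")
    out: dict = {}
    for (og, org), group in orthogroups.groupby(["orthogroup_id", "organism"]):
        candidates = []
        for pid in group["protein_id"]:
            if pid in quantified_peptide_counts:
                candidates.append((-quantified_peptide_counts[pid], pid))
            else:
                log.info("protein %s not quantified; ignored for orthogroup %s", pid, og)
        if candidates:
            out[(og, org)] = min(candidates)[1]
    return out
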