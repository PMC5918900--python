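"""Dataset-level trimming: decontamination, prevalence filtering, depth
normalisation and rarefaction curves.

The default pipeline order is depth normalisation, then control-pot
decontamination, with the prevalence filter applied upstream of both (it
mimics the artificial-OTU filter applied during OTU calling). Each step is a
pure function OtuDataset -> OtuDataset recording itself in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import OtuDataset, subset_dataset


@dataclass
class RarefactionCurve:
    """Expected number of distinct OTUs as a function of read depth."""
    sample_id: str
    grid: np.ndarray
    expected_richness: np.ndarray
    n_draws: int | None  # None => analytic (exact hypergeometric expectation)


def remove_control_otus(ds: OtuDataset) -> OtuDataset:
    """Drop every OTU detected in any control-substrate sample, everywhere.

    Decontamination is binary presence-based: one read in one control pot is
    enough to remove an OTU from all samples. The control samples themselves
    are dropped afterwards. With no controls the dataset is returned unchanged
    (plus a provenance warning).
    """
    ctrl_ids = ds.samples.index[ds.samples["role"] == "control_substrate"]
    if len(ctrl_ids) == 0:
        return ds.with_provenance({"step": "remove_control_otus",
                                   "warning": "no control_substrate samples; dataset unchanged"})
    contaminated = ds.counts.columns[(ds.counts.loc[ctrl_ids] > 0).any(axis=0)]
    keep_samples = [s for s in ds.counts.index if s not in set(ctrl_ids)]
    counts = ds.counts.loc[keep_samples, [c for c in ds.counts.columns if c not in set(contaminated)]]
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    return OtuDataset(counts, ds.taxonomy.loc[counts.columns], ds.samples.loc[keep_samples],
                      ds.provenance + [{"step": "remove_control_otus",
                                        "n_controls": int(len(ctrl_ids)),
                                        "removed_otus": sorted(contaminated)}])


def prevalence_filter(ds: OtuDataset, min_samples: int = 3) -> OtuDataset:
    """Keep only OTUs present (count>0) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > ds.n_samples:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {ds.n_samples}")
    prevalence = (ds.counts > 0).sum(axis=0)
    keep = ds.counts.columns[prevalence >= min_samples]
    counts = ds.counts[keep]
    return OtuDataset(counts, ds.taxonomy.loc[keep], ds.samples,
                      ds.provenance + [{"step": "prevalence_filter",
                                        "min_samples": int(min_samples),
                                        "n_removed": int(ds.n_otus - len(keep))}])


def _rarefy_row(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    # uniform subsample of reads without replacement (multivariate hypergeometric)
    return rng.multivariate_hypergeometric(row, depth)


def normalize_depth(ds: OtuDataset, depth: int, seed: int) -> OtuDataset:
    """Rarefy every sample to exactly ``depth`` reads, without replacement.

    Samples with fewer than ``depth`` total reads are dropped. Raises when no
    sample reaches the requested depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = ds.counts.sum(axis=1)
    keep = list(totals.index[totals >= depth])
    dropped = sorted(set(totals.index) - set(keep))
    if not keep:
        raise ValueError(f"depth {depth} exceeds every sample total (max {int(totals.max())})")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in sorted(keep):  # sorted: draw order independent of input order
        row = ds.counts.loc[sid].to_numpy()
        rows.append(row if row.sum() == depth else _rarefy_row(row, depth, rng))
    counts = pd.DataFrame(np.vstack(rows), index=sorted(keep), columns=ds.counts.columns)
    counts.index.name = "sample_id"
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    return OtuDataset(counts, ds.taxonomy.loc[counts.columns], ds.samples.loc[sorted(keep)],
                      ds.provenance + [{"step": "normalize_depth", "depth": int(depth),
                                        "seed": int(seed), "dropped_samples": dropped}])


def auto_depth(ds: OtuDataset, retain: float = 0.9) -> int:
    """Heuristic stand-in for choosing the rarefaction depth by eye: the
    largest depth with a single significant digit that retains at least
    ``retain`` of the samples."""
    totals = np.sort(ds.counts.sum(axis=1).to_numpy())
    totals = totals[totals > 0]  # read-free samples can never be rarefied
    if len(totals) == 0:
        raise ValueError("cannot pick a positive depth: no sample has reads")
    n = len(totals)
    # smallest total among the retained fraction
    cutoff = totals[int(np.floor((1 - retain) * n))]
    exp = int(np.floor(np.log10(cutoff)))
    lead = int(cutoff // 10 ** exp)
    return lead * 10 ** exp


def expected_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected number of distinct OTUs in a uniform subsample of
    ``depth`` reads drawn without replacement: sum_i 1 - C(T-c_i, d)/C(T, d)."""
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    total = int(c.sum())
    if depth > total:
        raise ValueError("depth exceeds sample total")
    # log C(T-c_i, d) - log C(T, d), with C(n, d)=0 when n < d
    def logcomb(n, k):
        n = np.asarray(n, dtype=float)
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    p_absent = np.zeros(len(c))
    ok = (total - c) >= depth
    p_absent[ok] = np.exp(logcomb(total - c[ok], depth) - logcomb(total, depth))
    return float(np.sum(1.0 - p_absent))


def rarefaction_curve(ds: OtuDataset, grid: np.ndarray | list[int],
                      n_draws: int | None = None, seed: int = 0) -> list[RarefactionCurve]:
    """Per-sample rarefaction curves over ``grid`` depths.

    Analytic mode (``n_draws=None``) uses the exact hypergeometric expectation;
    Monte-Carlo mode averages over ``n_draws`` uniform subsamples.
    Depths beyond a sample's total are reported as NaN for that sample.
    """
    grid = np.asarray(grid, dtype=np.int64)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    curves = []
    for sid in ds.counts.index:
        row = ds.counts.loc[sid].to_numpy()
        total = int(row.sum())
        vals = np.full(len(grid), np.nan)
        for i, d in enumerate(grid):
            if d > total:
                continue
            if n_draws is None:
                vals[i] = expected_richness(row, int(d))
            else:
                draws = [np.count_nonzero(_rarefy_row(row, int(d), rng)) for _ in range(n_draws)]
                vals[i] = float(np.mean(draws))
        curves.append(RarefactionCurve(sid, grid.copy(), vals, n_draws))
    return curves


def mean_curves(curves: list[RarefactionCurve], groups: pd.Series) -> pd.DataFrame:
    """Average per-sample curves by group label (e.g. role or marker)."""
    rows = []
    for c in curves:
        rows.append(pd.Series(c.expected_richness, index=c.grid, name=c.sample_id))
    mat = pd.DataFrame(rows)
    mat["group"] = groups.loc[mat.index].to_numpy()
    return mat.groupby("group").mean()
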