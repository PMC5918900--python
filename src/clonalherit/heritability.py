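"""Heritability index, richness-preserving null model, and standardized
effect sizes for vertical transmission of root microbiota.

The heritability index of an ecotype is the number of OTUs present in the
mother ramet's roots and in at least ``k`` (default 2) of its daughter
ramets' roots. To ask whether the observed index exceeds chance, each daughter
community is replaced by a uniform random sample, without replacement and of
identical richness, from a species pool — either the ecotype's own mother
community ("ecotype" mode) or the union of all mother communities ("regional"
mode, the default). Sampling probability is equal for all pool species,
deliberately ignoring abundance. The standardized effect size per ecotype is

    SES = (I_obs - mean(I_null)) / sd(I_null)

and transmission beyond chance is assessed with a one-sample t test of the
SES values against zero, alternative "greater".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import OtuDataset

_CHUNK = 2000  # null-model iterations simulated per block (memory bound)


@dataclass
class EcotypePresence:
    """Presence/absence view of one ecotype: the mother's OTU set, the
    daughters' OTU sets (ordered by stolon then position), and the pool used
    for null sampling."""
    ecotype: int
    mother_set: frozenset
    daughter_sets: list[frozenset]
    daughter_tags: list[tuple[str, int]]  # (position, stolon)
    pool: frozenset
    missing_mother: bool = False

    @property
    def daughter_richness(self) -> list[int]:
        return [len(s) for s in self.daughter_sets]


@dataclass
class NullModelConfig:
    n_iter: int = 9999
    k_min_daughters: int = 2
    pool_mode: str = "regional"  # or "ecotype"
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 1 <= self.k_min_daughters <= 4:
            raise ValueError("k_min_daughters must be in 1..4")
        if self.pool_mode not in ("regional", "ecotype"):
            raise ValueError(f"unknown pool_mode {self.pool_mode!r}")


@dataclass
class EcotypeHeritability:
    ecotype: int
    i_obs: int | None
    i_null: float | None
    sigma_null: float | None
    ses: float | None
    excluded: bool = False
    reason: str | None = None
    null_draws: np.ndarray | None = None


@dataclass
class HeritabilityResult:
    per_ecotype: list[EcotypeHeritability]
    t: float
    df: int
    p_one_sided: float
    alternative: str = "greater"
    shapiro_p: float | None = None
    config: NullModelConfig | None = None

    @property
    def ses_values(self) -> np.ndarray:
        return np.array([r.ses for r in self.per_ecotype if not r.excluded])


# ---------------------------------------------------------------------------
# presence construction
# ---------------------------------------------------------------------------

def build_presence(ds: OtuDataset, pool_mode: str = "regional") -> list[EcotypePresence]:
    """Build per-ecotype presence sets (count>0) for a single-marker dataset.

    An ecotype without a mother-root sample is still returned, flagged
    ``missing_mother`` (it is excluded downstream, never fatal here).
    """
    markers = set(ds.samples["marker"])
    if len(markers) > 1:
        raise ValueError(f"dataset mixes markers {sorted(markers)}; subset first")
    roots = ds.samples[ds.samples["role"].isin(["mother_root", "daughter_root"])]
    presences: list[EcotypePresence] = []
    mother_sets: dict[int, frozenset] = {}
    for eco in sorted(roots["ecotype"].dropna().unique()):
        eco = int(eco)
        rows = roots[roots["ecotype"] == eco]
        mothers = rows.index[rows["role"] == "mother_root"]
        mset = frozenset(ds.counts.columns[(ds.counts.loc[mothers] > 0).any(axis=0)]) \
            if len(mothers) else frozenset()
        mother_sets[eco] = mset
        daughters = rows[rows["role"] == "daughter_root"].copy()
        daughters = daughters.sort_values(["stolon", "position"])
        dsets, tags = [], []
        for sid, drow in daughters.iterrows():
            dsets.append(frozenset(ds.counts.columns[ds.counts.loc[sid] > 0]))
            tags.append((str(drow["position"]), int(drow["stolon"])))
        presences.append(EcotypePresence(eco, mset, dsets, tags, frozenset(),
                                         missing_mother=len(mothers) == 0))
    regional = frozenset().union(*mother_sets.values()) if mother_sets else frozenset()
    for ep in presences:
        ep.pool = regional if pool_mode == "regional" else mother_sets[ep.ecotype]
    return presences


def heritability_index(ep: EcotypePresence, k_min_daughters: int = 2) -> int:
    """Number of mother OTUs present in at least k daughter communities."""
    if len(ep.daughter_sets) < k_min_daughters:
        raise ValueError(f"ecotype {ep.ecotype}: {len(ep.daughter_sets)} daughters "
                         f"< k={k_min_daughters}")
    count = 0
    for otu in ep.mother_set:
        if sum(otu in d for d in ep.daughter_sets) >= k_min_daughters:
            count += 1
    return count


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def _mother_hits(rng: np.random.Generator, n_iter: int, m: int, pool_size: int,
                 richness: int) -> np.ndarray:
    """Boolean (n_iter, m): which of the m mother OTUs fall in a uniform
    richness-subset of the pool, drawn without replacement.

    Exploits exchangeability: the number of mother OTUs sampled is
    hypergeometric, and given that number the hit set is a uniform subset of
    the mother OTUs (taken as the positions of the smallest uniforms).
    """
    r = min(richness, pool_size)
    if m == 0 or r == 0:
        return np.zeros((n_iter, m), dtype=bool)
    if r == pool_size:
        return np.ones((n_iter, m), dtype=bool)
    h = rng.hypergeometric(m, pool_size - m, r, size=n_iter)
    u = rng.random((n_iter, m))
    order = np.argsort(u, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(m), (n_iter, m)), axis=1)
    return ranks < h[:, None]


def null_distribution(ep: EcotypePresence, cfg: NullModelConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Vector of ``cfg.n_iter`` heritability indices under the null model.

    Each iteration draws, for every daughter, an independent uniform sample
    without replacement from the pool with the daughter's observed richness,
    and scores it against the TRUE mother set. Mother OTUs outside the pool
    can never be drawn and contribute zero.
    """
    if not ep.pool:
        raise ValueError(f"ecotype {ep.ecotype}: empty pool")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pool_size = len(ep.pool)
    m = len(ep.mother_set & ep.pool)
    richnesses = ep.daughter_richness
    out = np.empty(cfg.n_iter, dtype=np.int64)
    done = 0
    while done < cfg.n_iter:
        block = min(_CHUNK, cfg.n_iter - done)
        shared = np.zeros((block, m), dtype=np.int16)
        for r in richnesses:
            shared += _mother_hits(rng, block, m, pool_size, r)
        out[done:done + block] = (shared >= cfg.k_min_daughters).sum(axis=1)
        done += block
    return out


def exact_null_expectation(ep: EcotypePresence, k_min_daughters: int = 2) -> float:
    """Closed-form expectation of the null heritability index.

    Under uniform sampling without replacement, each mother OTU in the pool is
    in daughter j with probability r_j/N independently across daughters, so
    E[I_null] = |mother ∩ pool| * P(Binomial-like >= k) with the >=k tail
    computed exactly over all inclusion patterns (Poisson binomial).
    """
    n = len(ep.pool)
    if n == 0:
        raise ValueError("empty pool")
    m = len(ep.mother_set & ep.pool)
    probs = [min(r / n, 1.0) for r in ep.daughter_richness]
    tail = 0.0
    for pattern in itertools.product([0, 1], repeat=len(probs)):
        if sum(pattern) >= k_min_daughters:
            w = 1.0
            for b, p in zip(pattern, probs):
                w *= p if b else (1.0 - p)
            tail += w
    return m * tail


# ---------------------------------------------------------------------------
# SES and the group-level test
# ---------------------------------------------------------------------------

def summarize_ecotype(ep: EcotypePresence, cfg: NullModelConfig,
                      rng: np.random.Generator | None = None,
                      keep_draws: bool = False) -> EcotypeHeritability:
    """Observed index, null mean/sd and SES for one ecotype; degenerate
    ecotypes (no mother, too few daughters, sigma_null=0) come back flagged
    ``excluded`` with a reason, never silently dropped."""
    if ep.missing_mother:
        return EcotypeHeritability(ep.ecotype, None, None, None, None, True, "no mother_root sample")
    if len(ep.daughter_sets) < cfg.k_min_daughters:
        return EcotypeHeritability(ep.ecotype, None, None, None, None, True,
                                   f"only {len(ep.daughter_sets)} daughters (k={cfg.k_min_daughters})")
    i_obs = heritability_index(ep, cfg.k_min_daughters)
    draws = null_distribution(ep, cfg, rng)
    i_null = float(draws.mean())
    sigma = float(draws.std(ddof=1))
    if sigma == 0.0:
        return EcotypeHeritability(ep.ecotype, i_obs, i_null, 0.0, None, True,
                                   "degenerate null distribution (sigma_null=0)",
                                   draws if keep_draws else None)
    ses = (i_obs - i_null) / sigma
    return EcotypeHeritability(ep.ecotype, i_obs, i_null, sigma, ses, False, None,
                               draws if keep_draws else None)


def compute_ses(records: list[EcotypeHeritability],
                config: NullModelConfig | None = None) -> HeritabilityResult:
    """Group-level one-sample t test of the SES values against 0 (greater).

    df = (number of non-excluded ecotypes) - 1. Raises when fewer than two
    ecotypes survive or when the SES values have zero variance.
    """
    ses = np.array([r.ses for r in records if not r.excluded], dtype=float)
    n = len(ses)
    if n < 2:
        raise ValueError(f"need >=2 non-excluded ecotypes, have {n}")
    sd = ses.std(ddof=1)
    if sd == 0.0:
        raise ValueError("SES values have zero variance; t undefined")
    t = ses.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = float(stats.t.sf(t, df))
    shapiro_p = float(stats.shapiro(ses).pvalue) if n >= 3 else None
    return HeritabilityResult(records, float(t), int(df), p, "greater", shapiro_p, config)


def run_heritability(ds: OtuDataset, cfg: NullModelConfig,
                     keep_draws: bool = False) -> HeritabilityResult:
    """Full heritability analysis of a single-marker root dataset."""
    presences = build_presence(ds, cfg.pool_mode)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(presences))
    records = [summarize_ecotype(ep, cfg, np.random.default_rng(s), keep_draws)
               for ep, s in zip(presences, seeds)]
    return compute_ses(records, cfg)
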