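"""Synthetic clonal-network microbiota generator.

Emulates the study design the analysis modules assume: 10 ecotypes, each a
clonal network of one mother ramet rooted in field soil and four daughter
ramets (2 stolons x 2 positions) rooted in sterile substrate, sequenced for
three markers. Mothers draw rich communities from a marker-wide regional
pool; daughters receive only a filtered "cohort" of the mother community,
with phylum-dependent transmission, multiplicative retention decay with
position (D2 < D1) and stolon order (2nd < 1st), archaea restricted to
mothers, and contaminant OTUs occupying unplanted control pots. Read counts
are multinomial over log-normal relative abundances at a fixed depth.

The generator's truth record (cohorts, per-daughter transmitted sets, all
parameters, the seed) is returned alongside the dataset so that recovery
tests can score every downstream estimate against the generating process.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import OtuDataset, write_otu_dataset
from .overlap import ReadSet

KINGDOMS = {"bacteria_16S": "Bacteria", "fungi_18S": "Fungi", "archaea_16S": "Archaea"}
_PREFIX = {"bacteria_16S": "B", "fungi_18S": "F", "archaea_16S": "A"}


@dataclass
class MarkerConfig:
    """Per-marker generator parameters (defaults echo the study's scale)."""
    marker: str
    phylum_sizes: dict[str, int]          # regional pool composition
    mother_richness: int                  # OTUs per mother community
    transmission: dict[str, float]        # per-phylum cohort inclusion probability
    retention: float = 0.8                # per-daughter retention of cohort OTUs
    sharing: float = 1.0                  # fraction of a daughter's transmitted OTUs
                                          # taken from the shared cohort; the rest are
                                          # drawn independently from the mother set
    position_decay: float = 0.85          # multiplier on retention at D2
    stolon_effect: float = 0.9            # multiplier on retention on stolon 2
    depth: int = 10000                    # reads per sample
    contaminant_pool: int = 0             # distinct contaminant OTUs
    control_occupancy: float = 0.5        # P(contaminant OTU occupies a control pot)
    contaminant_root_rate: float = 0.0    # P(contaminant OTU occurs in a root sample)
    lognormal_sigma: float = 1.0          # per-sample abundance noise
    occupancy_sigma: float = 1.2          # spread of pool-level OTU weights; couples
                                          # occupancy and abundance so rare OTUs are scarce
    ecotype_sigma: float = 0.6            # log-normal spread of a per-ecotype multiplier
                                          # on transmission (ecotypes differ widely in
                                          # how much of the mother pool they pass on)

    @property
    def pool_size(self) -> int:
        return sum(self.phylum_sizes.values())


def default_markers() -> dict[str, MarkerConfig]:
    return {
        "fungi_18S": MarkerConfig(
            marker="fungi_18S",
            phylum_sizes={"Ascomycota": 106, "Basidiomycota": 39, "Glomeromycota": 24,
                          "Zygomycota": 7, "Chytridiomycota": 4},
            mother_richness=40,
            # Basidiomycota pass the transmission filter far more readily
            transmission={"Ascomycota": 0.22, "Basidiomycota": 0.60, "Glomeromycota": 0.20,
                          "Zygomycota": 0.25, "Chytridiomycota": 0.25},
            retention=0.85, position_decay=0.9, stolon_effect=0.95,
            depth=5000, contaminant_pool=19, control_occupancy=0.4,
            contaminant_root_rate=0.0),
        "bacteria_16S": MarkerConfig(
            marker="bacteria_16S",
            phylum_sizes={"Proteobacteria": 2009, "Bacteroidetes": 715, "Acidobacteria": 180,
                          "Actinobacteria": 180, "Firmicutes": 120, "Verrucomicrobia": 60,
                          "Planctomycetes": 60, "Chloroflexi": 60},
            mother_richness=800,
            transmission={ph: 0.155 for ph in
                          ("Proteobacteria", "Bacteroidetes", "Acidobacteria", "Actinobacteria",
                           "Firmicutes", "Verrucomicrobia", "Planctomycetes", "Chloroflexi")},
            retention=0.8, position_decay=0.85, stolon_effect=0.9,
            depth=10000, contaminant_pool=400, control_occupancy=0.5,
            contaminant_root_rate=0.02),
        "archaea_16S": MarkerConfig(
            marker="archaea_16S",
            phylum_sizes={"Thaumarchaeota": 30},
            mother_richness=10,
            transmission={"Thaumarchaeota": 0.0},   # archaea never reach daughters
            depth=2000, contaminant_pool=0),
    }


@dataclass
class SyntheticConfig:
    n_ecotypes: int = 10
    n_controls: int = 3
    cohort_mode: str = "shared"   # "shared" cohort per ecotype, or "independent"
    markers: dict[str, MarkerConfig] = field(default_factory=default_markers)
    seed: int = 0

    def __post_init__(self):
        if self.cohort_mode not in ("shared", "independent"):
            raise ValueError(f"unknown cohort_mode {self.cohort_mode!r}")
        if self.n_ecotypes < 1 or self.n_controls < 0:
            raise ValueError("inconsistent config")
        for mc in self.markers.values():
            if not all(0.0 <= p <= 1.0 for p in mc.transmission.values()):
                raise ValueError("transmission probabilities must be in [0,1]")
            if mc.depth < 1:
                raise ValueError("depth must be >= 1")


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    seed: int
    mother_sets: dict          # marker -> {ecotype -> list of otu ids}
    cohorts: dict              # marker -> {ecotype -> list of otu ids}
    transmitted: dict          # marker -> {ecotype -> {sample_id -> list of otu ids}}
    contaminants: dict         # marker -> list of otu ids

    def expected_daughter_richness(self, marker: str, ecotype: int,
                                   position: str, stolon: int) -> float:
        mc = self.config.markers[marker]
        r = mc.retention
        if position == "D2":
            r *= mc.position_decay
        if stolon == 2:
            r *= mc.stolon_effect
        return len(self.cohorts[marker][ecotype]) * r


_DAUGHTERS = [("D1", 1), ("D2", 1), ("D1", 2), ("D2", 2)]


def _lognormal_counts(rng: np.random.Generator, otus: np.ndarray, depth: int,
                      sigma: float, base_weights: np.ndarray) -> np.ndarray:
    """Multinomial reads over base OTU weights perturbed by log-normal noise."""
    row = np.zeros(len(base_weights), dtype=np.int64)
    if len(otus) == 0:
        return row
    w = base_weights[otus] * rng.lognormal(0.0, sigma, size=len(otus))
    row[otus] = rng.multinomial(depth, w / w.sum())
    return row


def simulate_dataset(cfg: SyntheticConfig,
                     seed: int | None = None) -> tuple[OtuDataset, SyntheticTruth]:
    """Draw one full multi-marker dataset plus its generating truth."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    counts_blocks, meta_rows, tax_rows = [], [], []
    mother_sets, cohorts, transmitted, contaminants = {}, {}, {}, {}

    for marker, mc in cfg.markers.items():
        pref = _PREFIX[marker]
        otu_ids, phyla = [], []
        for ph, n in mc.phylum_sizes.items():
            for i in range(n):
                otu_ids.append(f"{pref}_{ph[:4]}_{i:04d}")
                phyla.append(ph)
        for i in range(mc.contaminant_pool):
            otu_ids.append(f"{pref}_cont_{i:04d}")
            phyla.append("contaminant")
        otu_ids = np.array(otu_ids)
        phyla = np.array(phyla)
        n_total = len(otu_ids)
        pool_idx = np.flatnonzero(phyla != "contaminant")
        cont_idx = np.flatnonzero(phyla == "contaminant")
        p_trans = np.zeros(n_total)
        for ph, p in mc.transmission.items():
            p_trans[phyla == ph] = p
        # pool-level OTU weights drive both who colonises a mother (occupancy)
        # and how many reads it gets (abundance)
        base_w = rng.lognormal(0.0, mc.occupancy_sigma, size=n_total)

        for oid, ph in zip(otu_ids, phyla):
            tax_rows.append({"otu_id": oid, "kingdom": KINGDOMS[marker], "phylum": ph})

        msets: dict[int, list] = {}
        ecos_cohorts: dict[int, list] = {}
        ecos_trans: dict[int, dict] = {}
        rows, row_ids = [], []

        # mothers first (the regional pool for independent mode needs them all)
        mother_idx: dict[int, np.ndarray] = {}
        pw = base_w[pool_idx] / base_w[pool_idx].sum()
        for eco in range(1, cfg.n_ecotypes + 1):
            mother_idx[eco] = np.sort(rng.choice(pool_idx, size=min(mc.mother_richness, len(pool_idx)),
                                                 replace=False, p=pw))
            msets[eco] = otu_ids[mother_idx[eco]].tolist()
        regional = np.unique(np.concatenate(list(mother_idx.values())))

        for eco in range(1, cfg.n_ecotypes + 1):
            midx = mother_idx[eco]
            sid = f"{pref}_E{eco:02d}_M"
            rows.append(_lognormal_counts(rng, midx, mc.depth, mc.lognormal_sigma, base_w))
            row_ids.append(sid)
            meta_rows.append({"sample_id": sid, "ecotype": eco, "role": "mother_root",
                              "position": "M", "stolon": None, "marker": marker})

            eco_factor = rng.lognormal(0.0, mc.ecotype_sigma)
            cohort = midx[rng.random(len(midx)) < np.minimum(p_trans[midx] * eco_factor, 1.0)]
            ecos_cohorts[eco] = otu_ids[cohort].tolist()
            ecos_trans[eco] = {}
            for pos, sto in _DAUGHTERS:
                did = f"{pref}_E{eco:02d}_{pos}.{sto}"
                r = mc.retention * (mc.position_decay if pos == "D2" else 1.0) \
                    * (mc.stolon_effect if sto == 2 else 1.0)
                if cfg.cohort_mode == "shared":
                    retained = rng.random(len(cohort)) < r
                    from_cohort = rng.random(len(cohort)) < mc.sharing
                    keep = cohort[retained & from_cohort]
                    # non-shared slots: independent draws from the mother set,
                    # preserving the expected transmitted richness
                    n_indep = int((retained & ~from_cohort).sum())
                    if n_indep:
                        indep = rng.choice(midx, size=min(n_indep, len(midx)), replace=False)
                        keep = np.unique(np.concatenate([keep, indep]))
                else:
                    # each daughter an independent uniform sample from the
                    # regional pool: exactly the null model's assembly process
                    target = int(round(p_trans[midx].sum() * r))
                    target = min(target, len(regional))
                    keep = np.sort(rng.choice(regional, size=target, replace=False))
                if mc.contaminant_root_rate > 0 and len(cont_idx):
                    extra = cont_idx[rng.random(len(cont_idx)) < mc.contaminant_root_rate]
                    keep = np.unique(np.concatenate([keep, extra]))
                ecos_trans[eco][did] = otu_ids[keep].tolist()
                rows.append(_lognormal_counts(rng, keep, mc.depth, mc.lognormal_sigma, base_w))
                row_ids.append(did)
                meta_rows.append({"sample_id": did, "ecotype": eco, "role": "daughter_root",
                                  "position": pos, "stolon": sto, "marker": marker})

        for c in range(1, cfg.n_controls + 1):
            sid = f"{pref}_CTRL{c}"
            occ = cont_idx[rng.random(len(cont_idx)) < mc.control_occupancy] \
                if len(cont_idx) else np.array([], dtype=int)
            rows.append(_lognormal_counts(rng, occ, mc.depth, mc.lognormal_sigma, base_w)
                        if len(occ) else np.zeros(n_total, dtype=np.int64))
            row_ids.append(sid)
            meta_rows.append({"sample_id": sid, "ecotype": None, "role": "control_substrate",
                              "position": "NA", "stolon": None, "marker": marker})

        counts_blocks.append(pd.DataFrame(np.vstack(rows), index=row_ids, columns=otu_ids))
        mother_sets[marker] = msets
        cohorts[marker] = ecos_cohorts
        transmitted[marker] = ecos_trans
        contaminants[marker] = otu_ids[cont_idx].tolist()

    counts = pd.concat(counts_blocks, axis=1).fillna(0).astype(np.int64)
    counts.index.name = "sample_id"
    counts.columns.name = "otu_id"
    taxonomy = pd.DataFrame(tax_rows).set_index("otu_id")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["ecotype"] = meta["ecotype"].astype("Int64")
    meta["stolon"] = meta["stolon"].astype("Int64")
    ds = OtuDataset(counts, taxonomy, meta,
                    provenance=[{"step": "simulate", "seed": int(seed),
                                 "cohort_mode": cfg.cohort_mode}])
    truth = SyntheticTruth(cfg, int(seed), mother_sets, cohorts, transmitted, contaminants)
    return ds, truth


# ---------------------------------------------------------------------------
# fixtures and read sets
# ---------------------------------------------------------------------------

def tiny_config(seed: int = 11) -> SyntheticConfig:
    """Two ecotypes, <=10 fungal OTUs, shallow depth: hand-checkable."""
    return SyntheticConfig(
        n_ecotypes=2, n_controls=1, seed=seed,
        markers={"fungi_18S": MarkerConfig(
            marker="fungi_18S",
            phylum_sizes={"Ascomycota": 5, "Basidiomycota": 3},
            mother_richness=5,
            transmission={"Ascomycota": 0.6, "Basidiomycota": 0.8},
            retention=0.9, position_decay=0.9, stolon_effect=0.95,
            depth=50, contaminant_pool=2, control_occupancy=0.8,
            lognormal_sigma=0.5, ecotype_sigma=0.0)})


def make_fixture(name: str, out_dir: str | Path | None = None,
                 seed: int | None = None) -> tuple[OtuDataset, SyntheticTruth]:
    """Generate the 'tiny' or 'study_like' fixture; optionally write the TSV
    triplet plus a JSON truth record."""
    if name == "tiny":
        cfg = tiny_config()
    elif name == "study_like":
        cfg = SyntheticConfig(seed=2024)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    ds, truth = simulate_dataset(cfg, seed)
    if out_dir is not None:
        out = Path(out_dir)
        write_otu_dataset(ds, out, prefix=name)
        payload = dataclasses.asdict(truth)
        payload["config"] = _config_dict(cfg)
        (out / f"{name}_truth.json").write_text(json.dumps(payload, indent=1, default=str))
    return ds, truth


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


_BASES = np.array(list("ACGT"))


def simulate_read_sets(marker: str = "fungi_18S", shared_fraction: float = 0.34,
                       n_mother_seqs: int = 60, n_daughter_reads: int = 1000,
                       read_length: int = 120, seed: int = 0) -> tuple[ReadSet, ReadSet, float]:
    """Mother and daughter read sets in which a configured fraction of the
    daughter reads copy mother sequences exactly (the rest are novel).
    Returns (mothers, daughters, realized shared fraction)."""
    rng = np.random.default_rng(seed)
    mother_seqs = ["".join(rng.choice(_BASES, read_length)) for _ in range(n_mother_seqs)]
    mothers = ReadSet("mother", marker)
    for s in mother_seqs:
        mothers.add(s, int(rng.integers(1, 20)))
    daughters = ReadSet("daughter", marker)
    n_shared = int(round(shared_fraction * n_daughter_reads))
    for _ in range(n_shared):
        daughters.add(mother_seqs[int(rng.integers(n_mother_seqs))])
    for _ in range(n_daughter_reads - n_shared):
        daughters.add("".join(rng.choice(_BASES, read_length)))
    return mothers, daughters, 100.0 * n_shared / n_daughter_reads
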