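"""End-to-end orchestration: preprocess -> heritability -> richness -> PLS-DA.

Markers are processed one at a time and never mixed in a statistical test.
Archaea receive descriptive output only (community summaries, no tests), since
they are absent from daughter roots by design. The report bundle is written
both as JSON (machine-readable) and as a short human-readable text file, with
the full provenance chain and every seed used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dataset import OtuDataset, read_otu_dataset, subset_dataset, validate_dataset
from .heritability import NullModelConfig, run_heritability
from .plsda import CONTRASTS, run_contrast
from .preprocess import auto_depth, normalize_depth, prevalence_filter, remove_control_otus
from .richness import fit_dilution, fit_mother_daughter, richness_table
from .simulate import SyntheticConfig, simulate_dataset

log = logging.getLogger("clonalherit")


@dataclass
class RunConfig:
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    simulate: SyntheticConfig | None = None
    depth: int | str = "auto"        # rarefaction depth or "auto"
    min_prevalence: int = 3
    k_min_daughters: int = 2
    n_iter: int = 9999
    pool_mode: str = "regional"
    contrasts: tuple[str, ...] = CONTRASTS
    n_perm: int = 999
    decontaminate_first: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        has_paths = self.counts is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("provide input paths XOR a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            raw["simulate"] = SyntheticConfig(**sim) if isinstance(sim, dict) else SyntheticConfig()
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)


def preprocess_marker(ds: OtuDataset, cfg: RunConfig, seed: int) -> OtuDataset:
    """Prevalence filter, control-pot decontamination, depth normalisation.

    Decontamination defaults to running before rarefaction: control presence
    is assessed at full depth (binary, so rarefaction could only lose
    contaminants, and control pots shallower than the normalisation depth
    would otherwise vanish before their OTUs are removed). Set
    ``decontaminate_first=False`` for the normalise-then-decontaminate order.
    """
    ds = prevalence_filter(ds, cfg.min_prevalence)
    if cfg.decontaminate_first:
        ds = remove_control_otus(ds)
    depth = auto_depth(ds) if cfg.depth == "auto" else int(cfg.depth)
    ds = normalize_depth(ds, depth, seed)
    if not cfg.decontaminate_first:
        ds = remove_control_otus(ds)
    return ds


def _model_dict(res) -> dict:
    return {"formula": res.formula, "transformation": res.transformation,
            "shapiro_p": res.shapiro_p, "n_obs": res.n_obs, "converged": res.converged,
            "effects": [dataclasses.asdict(e) for e in res.effects],
            "random_variances": res.random_variances}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report."""
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    if cfg.simulate is not None:
        ds, _truth = simulate_dataset(cfg.simulate, cfg.seed)
        source = {"simulate": True, "seed": cfg.seed, "cohort_mode": cfg.simulate.cohort_mode}
    else:
        ds = read_otu_dataset(cfg.counts, cfg.taxonomy, cfg.metadata)
        source = {"counts": cfg.counts, "taxonomy": cfg.taxonomy, "metadata": cfg.metadata}
    report: dict = {"version": __version__, "seed": cfg.seed, "source": source,
                    "validation": dataclasses.asdict(validate_dataset(ds)), "markers": {}}

    for marker in sorted(set(ds.samples["marker"])):
        mstart = time.time()
        sub = subset_dataset(ds, {"marker": marker}, description=f"marker={marker}")
        stage_seed = int(rng.integers(2 ** 31))
        try:
            pre = preprocess_marker(sub, cfg, stage_seed)
        except ValueError as exc:
            raise RuntimeError(f"stage preprocess failed for {marker}: {exc}") from exc
        roots = subset_dataset(pre, {"role": ["mother_root", "daughter_root"]},
                               description="roots", allow_empty=True)
        rt = richness_table(roots, by_phylum=True)
        entry: dict = {
            "n_samples": pre.n_samples, "n_otus": pre.n_otus,
            "depth": next(p["depth"] for p in pre.provenance if p.get("step") == "normalize_depth"),
            "richness_by_role": rt[rt["taxon_scope"] == "all"]
                .groupby("role")["richness"].mean().to_dict(),
        }
        daughters_present = (roots.samples["role"] == "daughter_root").any() and \
            rt[(rt["taxon_scope"] == "all") & (rt["role"] == "daughter_root")]["richness"].sum() > 0
        if marker == "archaea_16S" or not daughters_present:
            entry["note"] = ("descriptive only: no daughter-root communities "
                             "for this marker, no statistics computed")
            report["markers"][marker] = entry
            log.info("marker %s: descriptive only (%.1fs)", marker, time.time() - mstart)
            continue

        try:
            hcfg = NullModelConfig(cfg.n_iter, cfg.k_min_daughters, cfg.pool_mode,
                                   int(rng.integers(2 ** 31)))
            her = run_heritability(roots, hcfg)
        except Exception as exc:
            raise RuntimeError(f"stage heritability failed for {marker}: {exc}") from exc
        entry["heritability"] = {
            "t": her.t, "df": her.df, "p_one_sided": her.p_one_sided,
            "shapiro_p": her.shapiro_p, "pool_mode": cfg.pool_mode,
            "n_iter": cfg.n_iter, "k": cfg.k_min_daughters,
            "per_ecotype": [{k: v for k, v in dataclasses.asdict(r).items()
                             if k != "null_draws"} for r in her.per_ecotype],
        }
        try:
            entry["mother_daughter_model"] = _model_dict(fit_mother_daughter(rt))
            entry["dilution_model"] = _model_dict(fit_dilution(rt))
        except Exception as exc:
            raise RuntimeError(f"stage richness failed for {marker}: {exc}") from exc
        try:
            entry["plsda"] = {c: dataclasses.asdict(
                run_contrast(roots, c, cfg.n_perm, seed=int(rng.integers(2 ** 31))))
                for c in cfg.contrasts}
        except Exception as exc:
            raise RuntimeError(f"stage plsda failed for {marker}: {exc}") from exc
        entry["provenance"] = [
            {k: (v if not isinstance(v, list) or len(v) <= 10 else f"<{len(v)} items>")
             for k, v in p.items()} for p in pre.provenance]
        report["markers"][marker] = entry
        log.info("marker %s done (%.1fs)", marker, time.time() - mstart)

    report["runtime_s"] = round(time.time() - t0, 2)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
        (out / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    lines = [f"clonalherit {report['version']} | seed {report['seed']}"]
    for marker, e in report["markers"].items():
        lines.append(f"\n== {marker} ==")
        lines.append(f"samples {e['n_samples']}, OTUs {e['n_otus']}, depth {e['depth']}")
        for role, mean in e["richness_by_role"].items():
            lines.append(f"mean richness {role}: {mean:.1f}")
        if "note" in e:
            lines.append(e["note"])
            continue
        h = e["heritability"]
        lines.append(f"heritability SES t={h['t']:.2f} df={h['df']} "
                     f"p(one-sided)={h['p_one_sided']:.3g} pool={h['pool_mode']}")
        for name in ("mother_daughter_model", "dilution_model"):
            m = e.get(name)
            if m:
                for eff in m["effects"]:
                    lines.append(f"{name} {eff['term']}: F(1,{eff['df_den']})="
                                 f"{eff['f_stat']:.2f} p={eff['p_value']:.3g}")
        for c, r in e.get("plsda", {}).items():
            lines.append(f"PLS-DA {c}: ncomp={r['n_components']} "
                         f"explVarY={r['explained_variance_y']:.1f}% "
                         f"CVerr={r['cv_misclassification']:.1f}% p={r['p_value']:.3g}")
    return "\n".join(lines) + "\n"
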