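"""Heritability of the root microbiota: observed index per ecotype, the
richness-preserving null model (9999 iterations, regional pool, k=2), SES,
and the one-sided group t test. Archaea are skipped (absent from daughters).

Writes results/heritability_<marker>.tsv with a footer of group statistics.
"""

from pathlib import Path

import pandas as pd

from clonalherit.dataset import read_otu_dataset, subset_dataset
from clonalherit.heritability import NullModelConfig, run_heritability

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 5


def main() -> None:
    for marker in ("bacteria_16S", "fungi_18S"):
        pre = read_otu_dataset(ROOT / f"preprocessed/{marker}_counts.tsv",
                               ROOT / f"preprocessed/{marker}_taxonomy.tsv",
                               ROOT / f"preprocessed/{marker}_metadata.tsv")
        roots = subset_dataset(pre, {"role": ["mother_root", "daughter_root"]})
        res = run_heritability(roots, NullModelConfig(9999, 2, "regional", SEED))
        rows = [{"ecotype": r.ecotype, "i_obs": r.i_obs, "i_null": r.i_null,
                 "sigma_null": r.sigma_null, "ses": r.ses,
                 "excluded": r.excluded, "reason": r.reason}
                for r in res.per_ecotype]
        out = ROOT / f"heritability_{marker}.tsv"
        with out.open("w") as fh:
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
            fh.write(f"# t={res.t:.3f}\tdf={res.df}\tp_one_sided={res.p_one_sided:.3g}"
                     f"\tshapiro_p={res.shapiro_p:.3g}\tpool=regional\tk=2\tseed={SEED}\n")
        iobs = [r.i_obs for r in res.per_ecotype if r.i_obs is not None]
        print(f"{marker}: I_obs {min(iobs)}-{max(iobs)}, "
              f"t={res.t:.2f} df={res.df} p={res.p_one_sided:.2g} -> {out.name}")


if __name__ == "__main__":
    main()
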