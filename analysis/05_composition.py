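"""Community-composition contrasts by PLS-DA: mothers vs daughters, the
three-group position contrast, and 1st vs 2nd daughters; permutation p values
(199 label permutations here for a quick pass; the acceptance script uses 999).

Writes results/plsda_<marker>.tsv.
"""

from pathlib import Path

import pandas as pd

from clonalherit.dataset import read_otu_dataset, subset_dataset
from clonalherit.plsda import CONTRASTS, run_contrast

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 17
N_PERM = 199


def main() -> None:
    for marker in ("bacteria_16S", "fungi_18S"):
        pre = read_otu_dataset(ROOT / f"preprocessed/{marker}_counts.tsv",
                               ROOT / f"preprocessed/{marker}_taxonomy.tsv",
                               ROOT / f"preprocessed/{marker}_metadata.tsv")
        roots = subset_dataset(pre, {"role": ["mother_root", "daughter_root"]})
        rows = []
        for contrast in CONTRASTS:
            r = run_contrast(roots, contrast, N_PERM, seed=SEED)
            rows.append({"contrast": contrast, "classes": "/".join(r.classes),
                         "n_components": r.n_components,
                         "explained_variance_y_pct": round(r.explained_variance_y, 2),
                         "cv_misclassification_pct": round(r.cv_misclassification, 2),
                         "p_value": r.p_value, "n_perm": r.n_permutations})
            print(f"{marker} {contrast}: explVarY={r.explained_variance_y:.1f}% "
                  f"CVerr={r.cv_misclassification:.1f}% p={r.p_value:.3g}")
        pd.DataFrame(rows).to_csv(ROOT / f"plsda_{marker}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
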