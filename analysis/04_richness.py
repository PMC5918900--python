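"""Richness along the clonal network: mother-vs-daughter contrast and the
daughters-only dilution model (position + stolon), per marker and per phylum.

Writes richness tables and model summaries under results/richness/.
"""

from pathlib import Path

from clonalherit.dataset import read_otu_dataset, subset_dataset
from clonalherit.richness import (fit_dilution, fit_mother_daughter,
                                  phylum_models, richness_table)

ROOT = Path(__file__).resolve().parent.parent / "results"


def describe(name, res):
    lines = []
    for e in res.effects:
        lines.append(f"{name} {e.term}: est={e.estimate:+.3f} "
                     f"F(1,{e.df_den})={e.f_stat:.2f} p={e.p_value:.3g} "
                     f"[transform={res.transformation}]")
    return lines


def main() -> None:
    out = ROOT / "richness"
    out.mkdir(parents=True, exist_ok=True)
    for marker in ("bacteria_16S", "fungi_18S"):
        pre = read_otu_dataset(ROOT / f"preprocessed/{marker}_counts.tsv",
                               ROOT / f"preprocessed/{marker}_taxonomy.tsv",
                               ROOT / f"preprocessed/{marker}_metadata.tsv")
        roots = subset_dataset(pre, {"role": ["mother_root", "daughter_root"]})
        rt = richness_table(roots, by_phylum=True)
        rt.to_csv(out / f"{marker}_richness.tsv", sep="\t", index=False)
        lines = describe("mother_vs_daughter", fit_mother_daughter(rt))
        lines += describe("dilution", fit_dilution(rt))
        for ph, model in phylum_models(rt).items():
            if isinstance(model, str):
                lines.append(f"phylum {ph}: {model}")
            else:
                lines += describe(f"phylum {ph}", model)
        (out / f"{marker}_models.txt").write_text("\n".join(lines) + "\n")
        print(f"{marker}:")
        for ln in lines[:4]:
            print("  " + ln)


if __name__ == "__main__":
    main()
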