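"""Generate the study-scale synthetic dataset all later steps analyse.

Ten ecotypes, each a clonal network of one mother ramet (field soil) and four
daughter ramets (sterile substrate, 2 stolons x 2 positions), with root
communities for three markers and three unplanted control pots. Writes the
TSV triplet plus the generator truth under results/data/.
"""

from pathlib import Path

from clonalherit.simulate import make_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024


def main() -> None:
    ds, truth = make_fixture("study_like", OUT, seed=SEED)
    print(f"wrote {ds.n_samples} samples x {ds.n_otus} OTUs to {OUT} (seed {SEED})")
    for marker in ("bacteria_16S", "fungi_18S", "archaea_16S"):
        n = sum(len(v) for v in truth.cohorts.get(marker, {}).values())
        print(f"  {marker}: total transmitted-cohort OTUs across ecotypes: {n}")


if __name__ == "__main__":
    main()
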