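"""Simulate the in vitro irradiation experiment on a spotted miRNA array.

Two lymphoblastoid lines (ATM-proficient GM0536, ATM-deficient GM1526),
each mock-treated and irradiated, genes in triplicate with housekeeping
positive controls and bacterial negative controls. Plants a handful of
ATM-dependent IR effects, including one IR-induced dropout, and writes the
four probe-level tables plus the ground-truth table.
"""

from pathlib import Path

from radiomir import ArraySimConfig, simulate_array, write_array_table
from radiomir.pipeline import array_filename

OUT = Path(__file__).resolve().parent.parent / "results" / "arrays"

EFFECTS = {
    ("ATM_null", "hsa-mir-sim001"): 2.2,   # IR-induced, ATM-deficient only
    ("ATM_null", "hsa-mir-sim002"): 0.45,  # IR-repressed
    ("ATM_null", "hsa-mir-sim003"): 0.0,   # IR-induced dropout
    ("ATM_wt", "hsa-mir-sim004"): 1.8,     # ATM-proficient response
}


def main() -> None:
    cfg = ArraySimConfig(seed=20240901, n_mirnas=20, spot_cv=0.05, effects=EFFECTS)
    conditions, truth = simulate_array(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for cond in conditions.values():
        write_array_table(cond, OUT / array_filename(cond))
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"wrote {len(conditions)} array tables ({cfg.n_mirnas} miRNAs, triplicate spots) to {OUT}")
    print(f"planted effects: {len(EFFECTS)} (see truth.tsv)")


if __name__ == "__main__":
    main()
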