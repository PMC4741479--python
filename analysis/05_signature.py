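"""Cohort concordance screen: recover the signature and compare ATM levels.

Replays the validation analysis on the simulated cohort: per-miRNA arm
ratios vs untreated, Welch tests responder-vs-progressor, and the
directional-concordance screen against the packaged direction table. Also
compares ATM RPPA levels between response groups.
"""

from importlib import resources
from pathlib import Path

from radiomir import PipelineConfig, run_signature

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    with resources.as_file(resources.files("radiomir.data").joinpath("table1_screen.tsv")) as screen:
        res = run_signature(screen, ROOT / "cohort" / "cohort.tsv", PipelineConfig(), ROOT / "signature")
    members = [e for e in res["entries"] if e.concordant]
    print(f"concordant signature ({len(members)} miRNAs):")
    for e in members:
        print(
            f"  {e.mirna_id}: responder {e.direction_responder}, progressor "
            f"{e.direction_progressor}, in vitro {e.invitro_direction}, p={e.p_value:.2e}"
        )
    atm = res["atm"]
    print(
        f"ATM RPPA: responder mean {atm.mean_responder:.3f} vs progressor mean "
        f"{atm.mean_progressor:.3f}, p={atm.p_value:.2e} "
        f"({'lower in responders' if atm.direction < 0 else 'not lower'})"
    )
    print(f"tables -> {ROOT / 'signature'}")


if __name__ == "__main__":
    main()
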