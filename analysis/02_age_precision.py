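"""Age-reading precision and otolith-vertebra agreement.

Computes APE and ACV per structure from the triplicate reads and
regresses vertebral consensus age on otolith consensus age. With the
default reading-error settings (otolith SD 0.4 yr < vertebra SD 0.5 yr)
the otolith should come out as the more precise structure — the pattern
that justifies using otolith ages for growth modelling.
"""

from _common import RESULTS_DIR, load_tables
from cavegrowth import ageing, io_model
from cavegrowth.io_model import Structure


def main():
    _, readings, _ = load_tables()
    cmp = ageing.compare_structures(
        readings[Structure.OTOLITH], readings[Structure.VERTEBRA]
    )
    manifest = io_model.write_results(
        {
            "precision_summary": [cmp.otolith, cmp.vertebra],
            "structure_agreement": cmp.fit,
        },
        RESULTS_DIR / "precision",
    )
    for s in (cmp.otolith, cmp.vertebra):
        print(
            f"{s.structure.value:9s} APE {s.ape_percent:5.2f}%  "
            f"ACV {s.acv_percent:5.2f}%  (n = {s.n_fish})"
        )
    f = cmp.fit
    print(
        f"agreement: vertebra = {f.slope:.3f} x otolith + {f.intercept:+.3f}  "
        f"(R^2 = {f.r_squared:.3f})"
    )
    better = (
        "otolith" if cmp.otolith.acv_percent < cmp.vertebra.acv_percent else "vertebra"
    )
    print(f"more precise structure this run: {better}")
    print(f"wrote {len(manifest['files'])} tables -> results/precision/")


if __name__ == "__main__":
    main()
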