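"""Generate the synthetic confocal acquisitions used by the later stages.

Writes TIFF + JSON-sidecar scans under results/scans/: a raster series of
freely diffusing monomers (RICS/N&B input), a confined-entity oligomer
mixture, a two-colour complex mixture, and line scans across open, closed
and one-way cell walls.
"""

from pathlib import Path

from scanfcs.io import save_scan
from scanfcs.studies import (complex_study, oligomer_study, pcf_study,
                             rics_study)

OUT = Path("results/scans")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    jobs = {
        "rics_monomer_D2.45.tif": lambda: rics_study(D=2.45, seed=SEED),
        "nandb_oligomer_7.5pct.tif": lambda: oligomer_study(0.075, SEED),
        "cross_complex_15pct.tif": lambda: complex_study(0.15, SEED),
        "pcf_open_wall.tif": lambda: pcf_study(1.0, 1.0, SEED,
                                               n_lines=50_000),
        "pcf_closed_wall.tif": lambda: pcf_study(0.0, 0.0, SEED,
                                                 n_lines=50_000),
        "pcf_oneway_wall.tif": lambda: pcf_study(1.0, 0.0, SEED,
                                                 n_lines=50_000,
                                                 seed_side="left"),
    }
    for name, build in jobs.items():
        path = OUT / name
        series = build()
        save_scan(series, path)
        print(f"wrote {path} ({series.counts.shape})")


if __name__ == "__main__":
    main()
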