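#!/usr/bin/env python
"""Simulate the study-shaped data set.

Builds the 9-strain x 2-N-source x 6-Pi-level factorial design (3 biological
x 3 technical replicates, Mortierella strains excluded at Pi8), simulates the
936 HTS biomass spectra and the 972 ATR media spectra with known ground
truth, and writes everything under results/simulated/.
"""

from pathlib import Path

from ftirco import synthetic_data as sd
from ftirco.spectra_io import write_spectra

SEED = 1
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = sd.study_design()
    grown = [m for m in design if m.grew]
    measured = sd.expand_technical(design, tech_reps=3)
    print(
        f"design: {len(design)} biological samples, {len(grown)} grown, "
        f"{len(measured)} measured biomass spectra"
    )

    biomass, truth = sd.simulate_biomass_set(measured, seed=SEED)
    write_spectra(biomass, OUT / "biomass_raw.csv")
    truth.to_csv(OUT / "biomass_truth.tsv", sep="\t", index=False)

    media, media_truth = sd.simulate_media_set(design, seed=SEED)
    write_spectra(media, OUT / "media_raw.csv")
    media_truth.to_csv(OUT / "media_truth.tsv", sep="\t", index=False)
    n_media = int((media.meta["kind"] == "media_atr").sum())
    print(f"simulated {len(biomass)} biomass and {n_media} media spectra -> {OUT}")


if __name__ == "__main__":
    main()
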