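#!/usr/bin/env python
"""Preprocess the simulated biomass spectra along both branches.

Branch 1 (region analyses): Savitzky-Golay second derivative (window 11 for
the narrow lipid / chitin-chitosan bands, 61 for the broad polyphosphate
bands) -> EMSC -> technical-replicate averaging; 936 -> 312 spectra.
Branch 2 (overview): technical + biological averaging -> EMSC;
936 -> 104 spectra.
"""

from pathlib import Path

from ftirco.spectra_io import load_spectra, write_spectra
from ftirco.preprocess import preprocess_branch1, preprocess_branch2

IN = Path("results/simulated/biomass_raw.csv")
OUT = Path("results/preprocessed")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    raw = load_spectra(IN)
    print(f"loaded {len(raw)} raw biomass spectra")
    for window in (11, 61):
        b1 = preprocess_branch1(raw, window=window)
        write_spectra(b1, OUT / f"biomass_branch1_w{window}.csv")
        print(f"branch 1 (window {window}): {len(b1)} spectra")
    b2 = preprocess_branch2(raw)
    write_spectra(b2, OUT / "biomass_branch2.csv")
    print(f"branch 2 (overview): {len(b2)} spectra")


if __name__ == "__main__":
    main()
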