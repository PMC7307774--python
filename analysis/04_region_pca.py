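#!/usr/bin/env python
"""Region-restricted PCA of the branch-1 spectra, per nitrogen source.

The lipid, polyphosphate and chitin/chitosan spectral windows each get their
own PCA (per N-source split), using the derivative window bound to the
region: 11 points for the narrow lipid and chitin bands, 61 for the broad
polyphosphate bands.  PC1 then tracks the respective metabolite content.
"""

import json
from pathlib import Path

from ftirco.spectra_io import REGION_WINDOWS, load_spectra
from ftirco.chemometrics import run_region_pca

IN_DIR = Path("results/preprocessed")
OUT = Path("results/pca")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    explained = {}
    for region, window in REGION_WINDOWS.items():
        sset = load_spectra(IN_DIR / f"biomass_branch1_w{window}.csv")
        res = run_region_pca(sset, region, n_components=2)
        explained[region] = {}
        for split, r in res.items():
            explained[region][split] = [
                round(100 * f, 1) for f in r.explained_variance_fraction
            ]
            rows = [
                f"{sid}\t{s[0]:.6g}\t{s[1]:.6g}"
                for sid, s in zip(r.sample_ids, r.scores)
            ]
            (OUT / f"region_{region}_{split}_scores.tsv").write_text(
                "sample_id\tPC1\tPC2\n" + "\n".join(rows) + "\n"
            )
            print(
                f"{region} / {split}: PC1 explains "
                f"{explained[region][split][0]}% (window {window})"
            )
    (OUT / "region_explained.json").write_text(json.dumps(explained, indent=2))


if __name__ == "__main__":
    main()
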