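#!/usr/bin/env python
"""Whole-spectrum PCA of the condition-averaged (branch-2) spectra, split by
nitrogen source.

On yeast extract the strains separate into strain-specific clusters; on
ammonium sulphate the phosphate level drives the spread instead.  Writes
scores and explained variances under results/pca/.
"""

import json
from pathlib import Path

import numpy as np

from ftirco.spectra_io import load_spectra
from ftirco.chemometrics import pca

IN = Path("results/preprocessed/biomass_branch2.csv")
OUT = Path("results/pca")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sset = load_spectra(IN)
    explained = {}
    for n_source in ("YE", "AS"):
        sub = sset.where(n_source=n_source)
        res = pca(sub, n_components=2)
        explained[n_source] = [round(100 * f, 1) for f in res.explained_variance_fraction]
        header = "sample_id\tPC1\tPC2"
        rows = [
            f"{sid}\t{s[0]:.6g}\t{s[1]:.6g}"
            for sid, s in zip(res.sample_ids, res.scores)
        ]
        (OUT / f"overview_{n_source}_scores.tsv").write_text(
            header + "\n" + "\n".join(rows) + "\n"
        )
        np.savetxt(
            OUT / f"overview_{n_source}_loadings.tsv",
            np.column_stack([res.wavenumbers, res.loadings.T]),
            delimiter="\t",
            header="wavenumber_cm-1\tPC1\tPC2",
            comments="",
        )
        print(
            f"{n_source}: PC1 {explained[n_source][0]}%, "
            f"PC2 {explained[n_source][1]}% explained variance "
            f"({len(sub)} spectra)"
        )
    (OUT / "overview_explained.json").write_text(json.dumps(explained, indent=2))


if __name__ == "__main__":
    main()
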