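"""Population structure of the genotyped animals.

PCA of the chip-panel genomic relationship matrix (the two herds should
separate on PC1) and the realised Hudson Fst between populations.
Writes PC coordinates, variance shares and a scatter plot.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pigpred.pipeline import study_config
from pigpred.scenarios import pca_structure
from pigpred.simpop import simulate

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    data = simulate(study_config(SEED))
    panel = data.chip_panel
    pops = data.pedigree.table.set_index("id").loc[panel.ids, "population"]

    coords, shares = pca_structure(panel=panel, n_components=5)
    coords = coords.copy()
    coords["population"] = pops.to_numpy()
    coords.to_csv(RESULTS / "03_pca_coordinates.csv",
                  index_label="id", float_format="%.6f")
    pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(shares))],
                  "variance_share": shares}).to_csv(
        RESULTS / "03_pca_variance_shares.csv", index=False,
        float_format="%.6f")

    seq = data.seq_panel
    d1 = seq.dosages[(pops == "pop1").to_numpy()]
    d2 = seq.dosages[(pops == "pop2").to_numpy()]
    p1, p2 = d1.mean(axis=0) / 2, d2.mean(axis=0) / 2
    n1, n2 = 2 * d1.shape[0], 2 * d2.shape[0]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = float(np.mean(num) / np.mean(den))

    print(f"PC1 {100 * shares[0]:.1f}% / PC2 {100 * shares[1]:.1f}% of variance")
    print(f"realised Hudson Fst = {fst:.4f} (divergence knob "
          f"{data.config.divergence})")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for pop, sub in coords.groupby("population"):
            ax.scatter(sub["PC1"], sub["PC2"], s=8, label=pop, alpha=0.7)
        ax.set_xlabel(f"PC1 ({100 * shares[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * shares[1]:.1f}%)")
        ax.legend()
        fig.tight_layout()
        figdir = ROOT / "scratch" / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig.savefig(figdir / "03_pca.png", dpi=120)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
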