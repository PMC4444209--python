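"""Describe the metabolite table itself: PCA variance structure, taxon
contrasts (Tukey HSD), normality annotation, and Spearman correlation
networks per taxon subset with per-group degree summaries."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, RESULTS, SEED  # noqa: E402

from admixqtl import ancestry as anc  # noqa: E402
from admixqtl.io import read_phenotypes, read_table, write_table  # noqa: E402
from admixqtl.phenostruct import (  # noqa: E402
    degree_summary,
    layout_fr,
    normality_check,
    pca,
    spearman_network,
    tukey_contrasts,
)


def main() -> None:
    pheno = read_phenotypes(DATA / "phenotypes.tsv")
    Q = read_table(RESULTS / "ancestry.tsv")["Q"]
    taxon = anc.classify_taxon(Q, preset="network_hybrids")
    groups = pd.Series({t: t.rpartition("_")[0] for t in pheno.columns})

    res = pca(pheno, scale=True)
    write_table(res.explained_pct.to_frame(), RESULTS / "pca_variance.tsv")
    write_table(res.scores[["PC1", "PC2"]], RESULTS / "pca_scores.tsv")
    pc1, pc2 = res.explained_pct.iloc[0], res.explained_pct.iloc[1]
    print(f"PCA (38 traits, correlation matrix): PC1 {pc1:.1f}%, PC2 {pc2:.1f}%")

    non_normal = sum(normality_check(pheno[t])[1] < 0.05 for t in pheno.columns)
    print(f"Shapiro-Wilk: {non_normal}/{pheno.shape[1]} traits non-normal at "
          f"p<0.05 (rank correlations used throughout)")

    tuk = []
    for t in pheno.columns:
        tab = tukey_contrasts(pheno[t], taxon, alpha=0.05)
        tab.insert(0, "trait", t)
        tuk.append(tab)
    tuk = pd.concat(tuk, ignore_index=True)
    write_table(tuk, RESULTS / "tukey.tsv", index=False)
    n_sig = int(tuk.loc[tuk["group1"].ne(tuk["group2"]), "reject"].sum())
    print(f"Tukey HSD: {n_sig}/{len(tuk)} taxon contrasts significant at "
          f"adjusted p<0.05")

    frames = []
    for name in ("hybrid", "alba-like", "tremula-like"):
        sub = pheno[taxon == name]
        edges = spearman_network(sub, r_threshold=0.5, p_threshold=0.001,
                                 trait_groups=groups, seed=SEED)
        deg = degree_summary(edges, list(pheno.columns), groups)
        by_group = deg.groupby("group")["degree"].agg(["mean", "min", "max"])
        print(f"network, {name} (n={len(sub)}): {len(edges)} edges; "
              f"mean correlated pairs per trait "
              f"{deg['degree'].mean():.1f}")
        for g, row in by_group.iterrows():
            print(f"    {g:<18} mean {row['mean']:.1f} "
                  f"range {int(row['min'])}-{int(row['max'])}")
        edges.insert(0, "subset", name)
        if not edges.empty:
            frames.append(edges)
            if name == "hybrid":
                coords = layout_fr(edges, seed=SEED)
                write_table(coords, RESULTS / "network_layout_hybrid.tsv")
    cols = ["subset", "trait_a", "trait_b", "rho", "p", "group_a", "group_b"]
    all_edges = (pd.concat(frames, ignore_index=True)
                 if frames else pd.DataFrame(columns=cols))
    write_table(all_edges, RESULTS / "network.tsv", index=False)


if __name__ == "__main__":
    main()
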