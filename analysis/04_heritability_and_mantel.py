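"""Quantify the genetic component of each metabolite trait two ways:
paternity-corrected half-sib heritability (REML) in the common garden, and
Mantel correlations between |dQ| genomic distance and phenotypic distance in
the hybrid zones (all trees, and hybrids only at 0.01 < Q < 0.99)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, RESULTS, SEED, garden_config  # noqa: E402

from admixqtl import ancestry as anc  # noqa: E402
from admixqtl.io import read_phenotypes, read_table, write_table  # noqa: E402
from admixqtl.quantgen import (  # noqa: E402
    heritability_table,
    mantel,
    multiplier_from_cp,
    value_distance,
)


def main() -> None:
    # --- common garden h2
    fam = read_table(DATA / "families.tsv")
    gpheno = read_phenotypes(DATA / "family_phenotypes.tsv")
    truth_h2 = read_table(DATA / "truth_h2.tsv", index_col=None).set_index("trait")
    cp = garden_config().cp
    exact, rounded = multiplier_from_cp(cp)
    h2 = heritability_table(gpheno, fam["family"], multiplier=rounded)
    h2["h2_true"] = h2["trait"].map(truth_h2["h2_true"])
    write_table(h2, RESULTS / "heritability.tsv", index=False)
    print(f"Cp = {cp}: mean sib relatedness {1 / exact:.4f}, "
          f"multiplier {exact:.3f} -> {rounded}")
    for _, r in h2.iterrows():
        print(f"  {r['trait']:<22} h2 = {r['h2']:.2f} (true {r['h2_true']:.2f})")

    # --- Mantel in the hybrid zones
    pheno = read_phenotypes(DATA / "phenotypes.tsv")
    Q = read_table(RESULTS / "ancestry.tsv")["Q"]
    hybrids = anc.classify_taxon(Q, preset="mantel_hybrids") == "hybrid"
    qd_all = value_distance(Q)
    qd_hyb = value_distance(Q[hybrids])
    rows = []
    traits = [t for t in pheno.columns
              if t in set(truth_h2.index) or t.endswith("_03")]
    for i, t in enumerate(traits):
        res_a = mantel(qd_all, value_distance(pheno[t]), 999, seed=SEED + i)
        res_h = mantel(qd_hyb, value_distance(pheno.loc[hybrids, t]), 999,
                       seed=SEED + 1000 + i)
        rows.append({"trait": t, "r_all": res_a.r, "p_all": res_a.p,
                     "r_hybrids": res_h.r, "p_hybrids": res_h.p})
    out = pd.DataFrame(rows)
    write_table(out, RESULTS / "mantel.tsv", index=False)
    sig = out[out["p_all"] < 0.05]
    print(f"Mantel (999 permutations, {len(traits)} traits shown): "
          f"{len(sig)} significant at p<0.05 over all trees")
    for _, r in out.iterrows():
        print(f"  {r['trait']:<22} r = {r['r_all']:.3f} (p {r['p_all']:.3f}); "
              f"hybrids only r = {r['r_hybrids']:.3f} (p {r['p_hybrids']:.3f})")


if __name__ == "__main__":
    main()
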