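"""Generate the synthetic hybrid-zone study and common garden.

Writes genotypes, annotations, parental allele frequencies, phenotypes and
ground truth under results/study_data/, plus the common-garden family table
and seedling phenotypes.  All later analysis scripts read these files.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, garden_config, study_config  # noqa: E402

from admixqtl.io import write_table  # noqa: E402
from admixqtl.simulate import simulate_common_garden, simulate_hybrid_zone  # noqa: E402


def main() -> None:
    cfg = study_config()
    geno, ann, freqs, pheno, truth = simulate_hybrid_zone(cfg)
    write_table(geno, DATA / "genotypes.tsv")
    write_table(ann, DATA / "annotations.tsv")
    write_table(freqs, DATA / "freqs.tsv", index=False)
    write_table(pheno, DATA / "phenotypes.tsv")
    write_table(truth.Q.to_frame(), DATA / "truth_q.tsv")
    write_table(truth.ancestry, DATA / "truth_ancestry.tsv")
    qtl_truth = [
        {"trait": q.trait, "locus": f"L{q.locus + 1:03d}", "a": q.a, "d": q.d}
        for q in truth.qtl
    ]
    import pandas as pd

    write_table(pd.DataFrame(qtl_truth), DATA / "truth_qtl.tsv", index=False)

    gcfg = garden_config()
    fam, gpheno, gtruth = simulate_common_garden(gcfg)
    write_table(fam, DATA / "families.tsv")
    write_table(gpheno, DATA / "family_phenotypes.tsv")
    write_table(
        pd.DataFrame({"trait": list(gtruth.h2), "h2_true": list(gtruth.h2.values())}),
        DATA / "truth_h2.tsv", index=False,
    )

    n_hyb = (ann["taxon_true"] == "hybrid").sum()
    print(f"hybrid zones: {len(geno)} trees ({n_hyb} hybrids) x "
          f"{geno.shape[1] // 2} loci, {pheno.shape[1]} traits, "
          f"{len(truth.qtl)} planted QTL")
    print(f"common garden: {len(fam)} seedlings in {fam['family'].nunique()} "
          f"families (Cp = {gcfg.cp})")
    print(f"data written to {DATA}")


if __name__ == "__main__":
    main()
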