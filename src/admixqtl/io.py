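"""TSV formats, run configuration, and the end-to-end pipeline.

All tables are UTF-8 TSV with "NA" as the missing token and a one-line
``#`` provenance header (tool version + config hash — deliberately no
timestamps, so reruns with the same seed are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ancestry as anc_mod
from . import mapping, phenostruct, quantgen, selection
from .simulate import SimConfig, SimTruth, simulate_common_garden, simulate_hybrid_zone

__all__ = [
    "RunConfig",
    "read_genotypes",
    "read_phenotypes",
    "read_annotations",
    "read_freqs",
    "write_table",
    "read_table",
    "run_full_pipeline",
]

log = logging.getLogger(__name__)

NA = "NA"


class InputError(ValueError):
    """Invalid user input (bad file, bad config): CLI exit code 1."""


# ---------------------------------------------------------------------------
# low-level TSV

def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "", index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# admixqtl {__version__} config_hash={config_hash or 'none'}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index, lineterminator="\n")


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA], index_col=index_col)


def _check_unique_ids(df: pd.DataFrame, path) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"duplicated individual id {dup!r} in {path}")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Genotype TSV: id column then two columns per locus (``L001.1``,
    ``L001.2`` ...), integer allele codes, NA for missing."""
    df = read_table(path)
    _check_unique_ids(df, path)
    if df.shape[1] % 2 != 0:
        raise InputError(f"odd number of allele columns in {path}")
    bad = [c for c in df.columns if not c.rpartition(".")[2] in ("1", "2")]
    if bad:
        raise InputError(f"allele columns must end in .1/.2; got {bad[:3]}")
    log.info("genotypes: %d individuals, %d loci, %d missing calls",
             len(df), df.shape[1] // 2, int(df.isna().sum().sum()) // 2)
    return df.astype(float)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _check_unique_ids(df, path)
    try:
        df = df.astype(float)
    except ValueError as e:
        raise InputError(f"non-numeric phenotype cell in {path}: {e}") from None
    log.info("phenotypes: %d individuals x %d traits, %d NA cells",
             df.shape[0], df.shape[1], int(df.isna().sum().sum()))
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _check_unique_ids(df, path)
    return df


def read_freqs(path: str | Path) -> pd.DataFrame:
    df = read_table(path, index_col=None)
    need = {"locus", "allele", "freq_alba", "freq_tremula"}
    if not need <= set(df.columns):
        raise InputError(f"frequency table must have columns {sorted(need)}")
    return df


def align_ids(*tables: pd.DataFrame) -> list[pd.DataFrame]:
    """Check all tables cover the same individuals; error on mismatch."""
    base = tables[0].index
    for t in tables[1:]:
        if not base.equals(t.index):
            missing = base.symmetric_difference(t.index)
            raise InputError(f"individual ids differ between tables: {list(missing)[:5]}")
    return list(tables)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.  Unknown YAML keys reject."""

    genotypes: str | None = None
    phenotypes: str | None = None
    annotations: str | None = None
    freqs: str | None = None
    families: str | None = None
    family_phenotypes: str | None = None
    taxon_preset: str = "network_hybrids"
    mantel_taxon_preset: str = "mantel_hybrids"
    mapping_threshold: float = 4.0
    mantel_permutations: int = 999
    alpha: float = 0.05
    cp: float = 0.31
    network_r: float = 0.5
    network_p: float = 0.001
    seed: int = 0
    outdir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # outdir is excluded: where results land must not change their bytes
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.md5(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline

def run_full_pipeline(
    config: RunConfig,
    sim_config: SimConfig | None = None,
    truth: SimTruth | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute ancestry -> residualise -> map -> clines -> enrichment ->
    (h2) -> Mantel -> PCA/Tukey/networks, writing one TSV per stage.

    Inputs come from the configured paths; when no genotype path is given a
    synthetic hybrid-zone dataset is generated from ``sim_config`` (or the
    default study-like configuration) with the run seed.  Returns the result
    frames keyed by stage name.
    """
    out = Path(config.outdir)
    h = config.config_hash()
    results: dict[str, pd.DataFrame] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        results[name] = df
        write_table(df, out / f"{name}.tsv", config_hash=h, index=index)

    stage = "load"
    try:
        if config.genotypes:
            genotypes = read_genotypes(config.genotypes)
            phenotypes = read_phenotypes(config.phenotypes)
            annotations = read_annotations(config.annotations)
            freqs = read_freqs(config.freqs)
            align_ids(genotypes, phenotypes, annotations)
        else:
            cfg = sim_config or SimConfig()
            cfg.seed = config.seed
            genotypes, annotations, freqs, phenotypes, truth = simulate_hybrid_zone(cfg)
            emit("genotypes", genotypes)
            emit("phenotypes", phenotypes)
            emit("annotations", annotations)
            emit("freqs", freqs, index=False)

        stage = "ancestry"
        Q = anc_mod.estimate_Q(genotypes, freqs)
        lsa_tab = anc_mod.estimate_lsa(genotypes, freqs, Q)
        taxon = anc_mod.classify_taxon(Q, preset=config.taxon_preset)
        anc_df = pd.DataFrame({"Q": Q, "taxon": taxon})
        emit("ancestry", anc_df)
        emit("lsa", lsa_tab.lsa)

        stage = "residualize"
        residuals = mapping.residualize(phenotypes, annotations["locality"])
        emit("residuals", residuals)

        stage = "map"
        chrom = freqs.groupby("locus", sort=False)["chromosome"].first() \
            if "chromosome" in freqs.columns else None
        qtl = mapping.map_phenotypes(
            residuals, lsa_tab.lsa, threshold=config.mapping_threshold, chromosome=chrom
        )
        emit("qtl", qtl, index=False)

        stage = "clines"
        clines = selection.het_excess_table(lsa_tab.lsa, Q, alpha=config.alpha)
        emit("clines", clines, index=False)
        per_zone = {}
        for loc, ids in annotations.groupby("locality").groups.items():
            tab = selection.het_excess_table(
                lsa_tab.lsa.loc[ids], Q.loc[ids], alpha=config.alpha
            )
            per_zone[str(loc)] = tab.set_index("locus")["excess"]
        cross = selection.cross_zone_excess(per_zone)
        emit("clines_cross_zone", cross.rename("excess_ge2_zones").to_frame())

        stage = "enrichment"
        retained = set(qtl.loc[qtl["retained"], "locus"]) if not qtl.empty else set()
        if retained:
            flags = clines.set_index("locus")["excess"]
            odds, p, table = selection.qtl_enrichment(flags, retained)
            enr = table.reset_index()
            enr["odds_ratio"] = odds
            enr["p_one_sided"] = p
            emit("enrichment", enr, index=False)

        stage = "heritability"
        if config.families:
            fam_tab = read_annotations(config.families)
            fam_pheno = (
                read_phenotypes(config.family_phenotypes)
                if config.family_phenotypes
                else phenotypes
            )
            _, mult_round = quantgen.multiplier_from_cp(config.cp)
            h2 = quantgen.heritability_table(
                fam_pheno.loc[fam_tab.index], fam_tab["family"], multiplier=mult_round
            )
            emit("heritability", h2, index=False)

        stage = "mantel"
        rows = []
        hybrid_ids = anc_mod.classify_taxon(Q, preset=config.mantel_taxon_preset) == "hybrid"
        qd_all = quantgen.value_distance(Q)
        qd_hyb = quantgen.value_distance(Q[hybrid_ids]) if hybrid_ids.sum() >= 3 else None
        for i, t in enumerate(phenotypes.columns):
            td = quantgen.value_distance(phenotypes[t])
            res = quantgen.mantel(
                qd_all, td, config.mantel_permutations, seed=config.seed * 100003 + i, trait=t
            )
            row = {"trait": t, "r_all": res.r, "p_all": res.p}
            if qd_hyb is not None:
                td_h = quantgen.value_distance(phenotypes.loc[hybrid_ids, t])
                res_h = quantgen.mantel(
                    qd_hyb, td_h, config.mantel_permutations,
                    seed=config.seed * 100003 + 50000 + i, trait=t,
                )
                row |= {"r_hybrids": res_h.r, "p_hybrids": res_h.p}
            rows.append(row)
        emit("mantel", pd.DataFrame(rows), index=False)

        stage = "pca"
        pres = phenostruct.pca(phenotypes, scale=True)
        emit("pca_variance", pres.explained_pct.to_frame())
        emit("pca_scores", pres.scores[["PC1", "PC2"]])

        stage = "tukey"
        tuk_rows = []
        for t in phenotypes.columns:
            try:
                tk = phenostruct.tukey_contrasts(phenotypes[t], taxon, alpha=config.alpha)
            except ValueError:
                continue
            tk.insert(0, "trait", t)
            tuk_rows.append(tk)
        if tuk_rows:
            emit("tukey", pd.concat(tuk_rows, ignore_index=True), index=False)

        stage = "network"
        group_series = pd.Series(
            {t: t.rpartition("_")[0] for t in phenotypes.columns}, name="group"
        )
        net_frames = []
        subsets = {"hybrid": taxon == "hybrid",
                   "alba-like": taxon == "alba-like",
                   "tremula-like": taxon == "tremula-like"}
        for name, mask in subsets.items():
            if mask.sum() < 4:
                continue
            edges = phenostruct.spearman_network(
                phenotypes[mask], r_threshold=config.network_r,
                p_threshold=config.network_p, trait_groups=group_series, seed=config.seed,
            )
            edges.insert(0, "subset", name)
            if not edges.empty:
                net_frames.append(edges)
        network = (
            pd.concat(net_frames, ignore_index=True)
            if net_frames
            else pd.DataFrame(columns=["subset", "trait_a", "trait_b", "rho", "p",
                                       "group_a", "group_b"])
        )
        emit("network", network, index=False)

        stage = "summary"
        summary_rows = [
            {"quantity": "n_individuals", "value": float(len(phenotypes))},
            {"quantity": "n_loci", "value": float(lsa_tab.lsa.shape[1])},
            {"quantity": "n_traits", "value": float(phenotypes.shape[1])},
            {"quantity": "n_hybrids", "value": float((taxon == "hybrid").sum())},
            {"quantity": "n_candidate_qtl", "value": float(len(qtl))},
            {"quantity": "n_retained_qtl", "value": float(qtl["retained"].sum()) if not qtl.empty else 0.0},
            {"quantity": "n_excess_loci", "value": float(clines["excess"].sum())},
        ]
        if truth is not None and truth.qtl:
            true_pairs = {(q.trait, f"L{q.locus + 1:03d}") for q in truth.qtl}
            found = {(r.trait, r.locus) for r in qtl.itertuples() if r.retained}
            tp = len(true_pairs & found)
            summary_rows += [
                {"quantity": "qtl_sensitivity", "value": tp / len(true_pairs)},
                {"quantity": "qtl_fdr", "value": (len(found) - tp) / len(found) if found else 0.0},
            ]
        emit("summary", pd.DataFrame(summary_rows), index=False)
    except InputError:
        raise
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return results
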