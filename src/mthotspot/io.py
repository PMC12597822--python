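"""Tab-separated readers/writers for the pipeline's table contracts.

Variant tables, germline carrier tables, per-position annotations and
ranked gene lists are all plain TSV; expression matrices round-trip through
MatrixMarket triplets (plus barcode/feature TSVs) via :mod:`anndata`, or a
dense TSV for small fixtures. Simulation configs serialize to YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .enrichment import GermlineTable, DEFAULT_TOTAL_INDIVIDUALS
from .simulate import CohortSimConfig, EffectGene, SingleCellSimConfig, SpikedHotspot

VARIANT_DTYPES = {
    "sample_id": str,
    "pos": np.int64,
    "ref": str,
    "alt": str,
    "tumor_vaf": float,
    "normal_vaf": float,
    "alt_fwd": np.int64,
    "alt_rev": np.int64,
    "depth": np.int64,
    "tissue": str,
    "type": str,
}


def read_variant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=VARIANT_DTYPES)


def write_variant_table(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_germline_table(
    path, total_individuals: int = DEFAULT_TOTAL_INDIVIDUALS
) -> GermlineTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return GermlineTable(
        carriers=dict(zip(df["pos"].astype(int), df["carrier_count"].astype(int))),
        total_individuals=total_individuals,
    )


def write_germline_table(table: GermlineTable, path) -> None:
    pd.DataFrame(
        {"pos": list(table.carriers), "carrier_count": list(table.carriers.values())}
    ).sort_values("pos").to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_ranked_list(ranked: pd.DataFrame, path) -> None:
    """Two-column (gene, fisher_z) TSV for preranked enrichment tools."""
    ranked[["gene", "fisher_z"]].to_csv(path, sep="\t", index=False, header=False)


def read_ranked_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["gene", "fisher_z"])


# -- expression matrices ----------------------------------------------------


def write_expression_mtx(adata: ad.AnnData, outdir) -> None:
    """MatrixMarket triplet + barcodes.tsv / features.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(adata.X))
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", index=False, header=False
    )
    adata.obs.to_csv(outdir / "obs.tsv", sep="\t")


def read_expression_mtx(outdir) -> ad.AnnData:
    outdir = Path(outdir)
    X = sparse.csr_matrix(spio.mmread(outdir / "matrix.mtx"))
    barcodes = pd.read_csv(outdir / "barcodes.tsv", header=None)[0].astype(str)
    features = pd.read_csv(outdir / "features.tsv", header=None)[0].astype(str)
    obs_path = outdir / "obs.tsv"
    obs = (
        pd.read_csv(obs_path, sep="\t", index_col=0)
        if obs_path.exists()
        else pd.DataFrame(index=barcodes)
    )
    obs.index = obs.index.astype(str)
    return ad.AnnData(
        X=X, obs=obs.loc[barcodes], var=pd.DataFrame(index=pd.Index(features))
    )


def write_expression_dense(adata: ad.AnnData, path) -> None:
    X = adata.X
    X = np.asarray(X.todense() if sparse.issparse(X) else X)
    pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).to_csv(
        path, sep="\t"
    )


def read_expression_dense(path) -> ad.AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ad.AnnData(
        X=sparse.csr_matrix(df.to_numpy()),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )


# -- configs ----------------------------------------------------------------


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    if isinstance(cfg, CohortSimConfig):
        d["spiked_hotspots"] = [dataclasses.asdict(s) for s in cfg.spiked_hotspots]
        if cfg.signature is not None:
            d["signature"] = {f"{r}|{s}": w for (r, s), w in cfg.signature.items()}
    if isinstance(cfg, SingleCellSimConfig):
        d["effect_genes"] = [dataclasses.asdict(e) for e in cfg.effect_genes]
        d["covariate_loci"] = {k: list(v) for k, v in cfg.covariate_loci.items()}
    return d


def save_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_cohort_config(path) -> CohortSimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["spiked_hotspots"] = tuple(
        SpikedHotspot(**s) for s in d.get("spiked_hotspots", [])
    )
    if d.get("signature"):
        d["signature"] = {
            tuple(k.split("|")): w for k, w in d["signature"].items()
        }
    for key in ("het_beta", "normal_noise_beta"):
        if key in d:
            d[key] = tuple(d[key])
    d["tissues"] = tuple(d.get("tissues", ()))
    return CohortSimConfig(**d)


def load_singlecell_config(path) -> SingleCellSimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["effect_genes"] = tuple(EffectGene(**e) for e in d.get("effect_genes", []))
    d["covariate_loci"] = {
        k: tuple(v) for k, v in d.get("covariate_loci", {}).items()
    }
    for key in ("zero_beta", "het_beta"):
        if key in d:
            d[key] = tuple(d[key])
    return SingleCellSimConfig(**d)
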