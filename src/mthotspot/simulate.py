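"""Synthetic cohorts, germline tables, annotations and single-cell data.

These generators reproduce the statistical structure the downstream
analyses assume, so that every stage can be exercised and validated without
any controlled-access download:

* **Cohort variant tables** — each tumor acquires a Poisson number of
  background somatic SNVs placed according to a strand/region-asymmetric
  substitution signature (C>T and T>C elevated on the reference strand
  outside the control region, mirrored inside it), plus optional spiked
  hotspot alleles carried per tumor with fixed probability. Emitted records
  mimic the cohort table contract: tumor/normal heteroplasmies,
  strand-split alt read support, depth and tissue.
* **Germline carrier tables** — sparse position -> homoplasmic carrier
  counts with constrained (0-1 carriers) and polymorphic (>= 2) positions;
  unlisted positions are implicitly zero.
* **Per-position annotations** — secondary-structure classes and
  conservation rates over the rRNA genes.
* **Single-cell data** — per-cell heteroplasmy drawn from a zero-skewed
  mixture (point-mass-like low component + Beta component), binomially
  sampled allele counts at the genotyped loci, and overdispersed
  (gamma-Poisson) expression counts in which designated effect genes
  respond to heteroplasmy through a step, hinge or logistic dosage link.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .enrichment import GermlineTable, DEFAULT_TOTAL_INDIVIDUALS, STRUCTURE_CLASSES
from .reference import BASES, MtReference

SUBSTITUTIONS = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)

#: Strand/region-asymmetric default signature: heavy-strand C>T and
#: light-strand T>C dominate outside the control region; the asymmetry is
#: mirrored (G>A / A>G on the reference strand) inside it.
DEFAULT_SIGNATURE: dict[tuple[str, str], float] = {}
for _sub in SUBSTITUTIONS:
    DEFAULT_SIGNATURE[("noncontrol", _sub)] = 0.25
    DEFAULT_SIGNATURE[("control", _sub)] = 0.25
DEFAULT_SIGNATURE[("noncontrol", "C>T")] = 10.0
DEFAULT_SIGNATURE[("noncontrol", "T>C")] = 10.0
DEFAULT_SIGNATURE[("noncontrol", "G>A")] = 1.0
DEFAULT_SIGNATURE[("noncontrol", "A>G")] = 1.0
DEFAULT_SIGNATURE[("control", "G>A")] = 10.0
DEFAULT_SIGNATURE[("control", "A>G")] = 10.0
DEFAULT_SIGNATURE[("control", "C>T")] = 1.0
DEFAULT_SIGNATURE[("control", "T>C")] = 1.0

DEFAULT_TISSUES = ("breast", "colorectal", "lung", "renal", "prostate", "ovary")


class SimConfigError(ValueError):
    """Raised for configurations that could never produce a valid dataset."""


@dataclass(frozen=True)
class SpikedHotspot:
    """A hotspot allele carried by each tumor independently with ``prob``."""

    pos: int
    alt: str
    prob: float


@dataclass
class CohortSimConfig:
    """Study conditions for the cohort generator.

    ``mean_mutations_per_tumor`` defaults to 1.4, the per-tumor somatic
    mutation burden observed in population-scale tumor mtDNA sequencing
    (roughly one mutation in every two tumors once multi-mutant tumors are
    averaged in). Heteroplasmies live on (0.05, 1] — the calling floor —
    and matched-normal noise on [0, 0.01).
    """

    n_tumors: int = 5000
    mean_mutations_per_tumor: float = 1.4
    signature: Mapping[tuple[str, str], float] | None = None
    spiked_hotspots: tuple[SpikedHotspot, ...] = ()
    het_beta: tuple[float, float] = (1.2, 3.0)
    min_vaf: float = 0.05
    normal_noise_beta: tuple[float, float] = (1.0, 30.0)
    mean_depth: float = 1000.0
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    truncating_prob: float = 0.05
    seed: int = 0


def _position_alt_weights(
    ref: MtReference, signature: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """(L, 4) array of per-position, per-alt-base signature weights."""
    L = ref.length
    seq_idx = np.array([BASES.index(b) for b in ref.sequence])
    control = ref._control_mask
    W = np.zeros((L, 4))
    for (region, sub), w in signature.items():
        if w < 0:
            raise SimConfigError(f"negative signature weight for {region}, {sub}")
        r, a = sub.split(">")
        mask = (seq_idx == BASES.index(r)) & (
            control if region == "control" else ~control
        )
        W[mask, BASES.index(a)] = w
    return W


def expected_substitution_spectrum(
    ref: MtReference, signature: Mapping[tuple[str, str], float] | None = None
) -> pd.Series:
    """Expected (region, substitution) probabilities under the signature.

    This is the distribution the empirical spectrum of a large simulated
    cohort converges to; useful as a goodness-of-fit target.
    """
    signature = signature or DEFAULT_SIGNATURE
    W = _position_alt_weights(ref, signature)
    control = ref._control_mask
    seq_idx = np.array([BASES.index(b) for b in ref.sequence])
    probs = {}
    for region, mask in (("noncontrol", ~control), ("control", control)):
        for sub in SUBSTITUTIONS:
            r, a = sub.split(">")
            m = mask & (seq_idx == BASES.index(r))
            probs[(region, sub)] = W[m, BASES.index(a)].sum()
    s = pd.Series(probs)
    return s / s.sum()


def simulate_cohort(
    ref: MtReference, cfg: CohortSimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort variant table and the spiked-hotspot truth set.

    Returns ``(calls, truth)``: ``calls`` has one row per (tumor, position)
    mutation with columns ``sample_id, pos, ref, alt, tumor_vaf,
    normal_vaf, alt_fwd, alt_rev, depth, tissue, type, truncating``;
    ``truth`` lists the spiked positions/alleles and their per-tumor
    probabilities. Row count equals the number of per-tumor mutations after
    within-tumor deduplication.
    """
    rng = np.random.default_rng(cfg.seed)
    signature = cfg.signature or DEFAULT_SIGNATURE
    for sp in cfg.spiked_hotspots:
        if ref.in_blacklist(sp.pos):
            raise SimConfigError(
                f"spiked hotspot at blacklisted position {sp.pos} could never "
                "survive filtering"
            )
        if sp.alt == ref.base(sp.pos):
            raise SimConfigError(f"spike alt equals reference base at {sp.pos}")
        if not 0 <= sp.prob <= 1:
            raise SimConfigError("spike probability must lie in [0, 1]")

    W = _position_alt_weights(ref, signature)
    flat = W.ravel()
    total_w = flat.sum()

    # Background: Poisson per tumor, positions/alts ~ signature weights.
    n_bg = rng.poisson(cfg.mean_mutations_per_tumor, size=cfg.n_tumors)
    total_bg = int(n_bg.sum())
    tumor_of = np.repeat(np.arange(cfg.n_tumors), n_bg)
    if total_bg and total_w > 0:
        flat_idx = rng.choice(flat.size, size=total_bg, p=flat / total_w)
        bg_pos = flat_idx // 4 + 1
        bg_alt = np.array(list(BASES))[flat_idx % 4]
    else:
        bg_pos = np.empty(0, dtype=np.int64)
        bg_alt = np.empty(0, dtype="<U1")
        tumor_of = np.empty(0, dtype=np.int64)

    # Spikes: independent Bernoulli carriers per tumor.
    sp_tumor, sp_pos, sp_alt = [], [], []
    for sp in cfg.spiked_hotspots:
        carriers = np.flatnonzero(rng.random(cfg.n_tumors) < sp.prob)
        sp_tumor.append(carriers)
        sp_pos.append(np.full(carriers.size, sp.pos, dtype=np.int64))
        sp_alt.append(np.full(carriers.size, sp.alt, dtype="<U1"))
    if sp_tumor:
        tumor_of = np.concatenate([tumor_of, *sp_tumor])
        bg_pos = np.concatenate([bg_pos, *sp_pos])
        bg_alt = np.concatenate([bg_alt, *sp_alt])

    df = pd.DataFrame({"tumor": tumor_of, "pos": bg_pos, "alt": bg_alt})
    df = df.drop_duplicates(subset=["tumor", "pos"], keep="last")
    df = df.sort_values(["tumor", "pos"], kind="mergesort").reset_index(drop=True)
    m = len(df)

    seq = np.array(list(ref.sequence))
    tumor_vaf = cfg.min_vaf + (1 - cfg.min_vaf) * rng.beta(*cfg.het_beta, size=m)
    normal_vaf = 0.01 * rng.beta(*cfg.normal_noise_beta, size=m)
    depth = rng.poisson(cfg.mean_depth, size=m)
    alt_total = np.maximum(rng.binomial(depth, tumor_vaf), 1)
    alt_fwd = rng.binomial(alt_total, 0.5)

    tissue_of_tumor = rng.choice(cfg.tissues, size=cfg.n_tumors)
    gene_idx = ref.gene_index_array[df["pos"].to_numpy() - 1]
    gene_names = np.array([g.name for g in ref.genes])
    is_coding = np.array(
        [
            gi >= 0
            and "RNR" not in gene_names[gi]
            and not gene_names[gi].split("-", 1)[-1].startswith("T")
            for gi in gene_idx
        ]
    )
    truncating = is_coding & (rng.random(m) < cfg.truncating_prob)

    calls = pd.DataFrame(
        {
            "sample_id": np.char.add("T", np.char.zfill(
                df["tumor"].to_numpy().astype(str), 5)),
            "pos": df["pos"].to_numpy(),
            "ref": seq[df["pos"].to_numpy() - 1],
            "alt": df["alt"].to_numpy(),
            "tumor_vaf": tumor_vaf,
            "normal_vaf": normal_vaf,
            "alt_fwd": alt_fwd,
            "alt_rev": alt_total - alt_fwd,
            "depth": depth,
            "tissue": tissue_of_tumor[df["tumor"].to_numpy()],
            "type": "SNV",
            "truncating": truncating,
        }
    )
    truth = pd.DataFrame(
        {
            "pos": [sp.pos for sp in cfg.spiked_hotspots],
            "alt": [sp.alt for sp in cfg.spiked_hotspots],
            "prob": [sp.prob for sp in cfg.spiked_hotspots],
        }
    )
    return calls, truth


# ---------------------------------------------------------------------------
# Germline carrier tables and annotations


def simulate_germline_table(
    ref: MtReference,
    n_constrained: int,
    n_polymorphic: int,
    total_individuals: int = DEFAULT_TOTAL_INDIVIDUALS,
    seed: int = 0,
    positions: Sequence[int] | None = None,
) -> GermlineTable:
    """Sparse carrier-count table with constrained and polymorphic positions.

    Constrained positions receive 0 or 1 homoplasmic carriers, polymorphic
    positions at least 2 (geometric tail). Positions not drawn are simply
    absent, so lookups read them as 0 carriers.
    """
    pool = np.asarray(positions) if positions is not None else np.arange(
        1, ref.length + 1
    )
    if n_constrained + n_polymorphic > pool.size:
        raise SimConfigError("more positions requested than available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_constrained + n_polymorphic, replace=False)
    counts = {}
    for pos in chosen[:n_constrained]:
        counts[int(pos)] = int(rng.integers(0, 2))
    for pos in chosen[n_constrained:]:
        counts[int(pos)] = 2 + int(rng.geometric(0.002))
    return GermlineTable(carriers=counts, total_individuals=total_individuals)


def simulate_annotations(
    ref: MtReference,
    seed: int = 0,
    genes: Sequence[str] = ("MT-RNR1", "MT-RNR2"),
    class_probs: Sequence[float] = (0.55, 0.15, 0.30),
    conservation_beta: tuple[float, float] = (5.0, 2.0),
    elevated_positions: Sequence[int] | None = None,
    elevated_beta: tuple[float, float] = (9.0, 1.5),
) -> pd.DataFrame:
    """Secondary-structure classes and conservation rates over rRNA genes.

    Every position of the named genes gets exactly one structure class
    (``WC`` / ``non-WC`` / ``loop-or-other``, probabilities
    ``class_probs``) and a conservation rate in [0, 1] (fraction of species
    sharing the reference base). ``elevated_positions`` draw their
    conservation from a right-shifted distribution.
    """
    if not np.isclose(sum(class_probs), 1.0):
        raise SimConfigError("class probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    pos = np.concatenate([ref.gene_positions(g) for g in genes])
    classes = rng.choice(STRUCTURE_CLASSES, size=pos.size, p=list(class_probs))
    cons = rng.beta(*conservation_beta, size=pos.size)
    if elevated_positions is not None:
        hi = np.isin(pos, np.asarray(elevated_positions))
        cons[hi] = rng.beta(*elevated_beta, size=int(hi.sum()))
    return pd.DataFrame(
        {"pos": pos, "structure_class": classes, "conservation": cons}
    )


# ---------------------------------------------------------------------------
# Single-cell generator


@dataclass(frozen=True)
class EffectGene:
    """A gene whose expression responds to heteroplasmy with threshold ``theta``.

    ``lfc`` is the log2 fold change at full dosage: applied wholesale above
    the threshold (``link="step"``), scaled linearly with dosage above it
    (``"hinge"``), through a smooth logistic ramp (``"logistic"``), or as a
    rise-then-fall response (``"compensatory"``): a mild compensatory
    log2 increase of ``comp_lfc`` accumulating below the threshold, then
    the ``lfc`` decline above it — the dosage response seen for
    mitochondrial transcripts, where sub-threshold heteroplasmy is buffered
    by upregulation before the phenotype switches on. Negative ``lfc``
    means expression declines with heteroplasmy.
    """

    gene: str
    theta: float
    lfc: float
    link: str = "hinge"
    comp_lfc: float = 1.0


def dosage_multiplier(
    h: np.ndarray,
    theta: float,
    lfc: float,
    link: str,
    comp_lfc: float = 1.0,
    logistic_scale: float = 0.05,
) -> np.ndarray:
    """Multiplicative expression effect of heteroplasmy ``h`` in [0, 1]."""
    h = np.asarray(h, dtype=float)
    if link == "step":
        e = lfc * (h > theta)
    elif link == "hinge":
        e = lfc * np.clip((h - theta) / max(1.0 - theta, 1e-12), 0.0, 1.0)
    elif link == "logistic":
        e = lfc / (1.0 + np.exp(-(h - theta) / logistic_scale))
    elif link == "compensatory":
        e = comp_lfc * np.minimum(h, theta) / max(theta, 1e-12) + lfc * np.clip(
            (h - theta) / max(1.0 - theta, 1e-12), 0.0, 1.0
        )
    else:
        raise ValueError(f"unknown link {link!r}")
    return 2.0 ** e


@dataclass
class SingleCellSimConfig:
    """Study conditions for the single-cell generator.

    The heteroplasmy mixture (``zero_weight`` of cells from a near-zero
    Beta component, the rest from a broad Beta) reproduces distributions
    strongly skewed towards zero with a median around 0.33 under the
    defaults. Locus coverage is gamma-Poisson with mean 120, overlapping
    the 25-250x confidence window used by the cell QC. A configurable
    fraction of cells deliberately violates QC so the filters have work to
    do.
    """

    n_cells: int = 5000
    zero_weight: float = 0.30
    zero_beta: tuple[float, float] = (0.6, 12.0)
    het_beta: tuple[float, float] = (2.0, 2.2)
    coverage_mean: float = 120.0
    coverage_shape: float = 8.0
    n_genes: int = 200
    effect_genes: tuple[EffectGene, ...] = ()
    baseline_log_mean: float = 1.3
    baseline_log_sd: float = 0.8
    nb_size: float = 2.0
    dropout: float = 0.05
    covariate_loci: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "m.9369": (2.0, 4.8),
            "m.1230": (0.5, 7.9),
            "m.1233": (0.5, 9.2),
        }
    )
    primary_locus: str = "m.1227"
    qc_violation_rate: float = 0.03
    seed: int = 0


def heteroplasmy_mixture_cdf(cfg: SingleCellSimConfig, h: float) -> float:
    """CDF of the configured heteroplasmy mixture at ``h`` (closed form)."""
    return float(
        cfg.zero_weight * stats.beta.cdf(h, *cfg.zero_beta)
        + (1 - cfg.zero_weight) * stats.beta.cdf(h, *cfg.het_beta)
    )


def simulate_singlecell(
    cfg: SingleCellSimConfig,
) -> tuple[pd.DataFrame, ad.AnnData, dict]:
    """Generate single-cell allele counts, expression, and ground truth.

    Returns ``(allele_counts, adata, truth)``:

    * ``allele_counts`` — long table (cell_id, locus, alt, ref) covering the
      primary locus and the covariate loci;
    * ``adata`` — cells x genes raw counts with ``obs`` QC fields
      (``n_features``, ``pct_mito``);
    * ``truth`` — the latent per-cell heteroplasmies, covariate
      heteroplasmies, and the effect-gene table.
    """
    if not 0 <= cfg.zero_weight <= 1:
        raise SimConfigError("zero_weight must lie in [0, 1]")
    n_eff = len(cfg.effect_genes)
    if n_eff > cfg.n_genes:
        raise SimConfigError("more effect genes than genes")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells

    # Latent heteroplasmies.
    from_zero = rng.random(n) < cfg.zero_weight
    h = np.where(
        from_zero, rng.beta(*cfg.zero_beta, size=n), rng.beta(*cfg.het_beta, size=n)
    )
    cov_het = {
        locus: rng.beta(a, b, size=n) for locus, (a, b) in cfg.covariate_loci.items()
    }

    # Allele counts at each genotyped locus (binomial in true heteroplasmy).
    cell_ids = np.array([f"C{i:05d}" for i in range(n)])
    loci = {cfg.primary_locus: h, **cov_het}
    frames = []
    for locus, het in loci.items():
        lam = rng.gamma(cfg.coverage_shape, cfg.coverage_mean / cfg.coverage_shape, n)
        cov = rng.poisson(lam)
        alt = rng.binomial(cov, het)
        frames.append(
            pd.DataFrame(
                {"cell_id": cell_ids, "locus": locus, "alt": alt, "ref": cov - alt}
            )
        )
    allele_counts = pd.concat(frames, ignore_index=True)

    # Expression: gamma-Poisson counts, effect genes modulated by dosage.
    names = [eg.gene for eg in cfg.effect_genes] + [
        f"G{i:04d}" for i in range(cfg.n_genes - n_eff)
    ]
    if len(set(names)) != cfg.n_genes:
        raise SimConfigError("gene names must be unique")
    mu_g = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    mu = np.tile(mu_g, (n, 1))
    for j, eg in enumerate(cfg.effect_genes):
        mu[:, j] = mu[:, j] * dosage_multiplier(
            h, eg.theta, eg.lfc, eg.link, comp_lfc=eg.comp_lfc
        )
    p_nb = cfg.nb_size / (cfg.nb_size + mu)
    counts = rng.negative_binomial(cfg.nb_size, p_nb)
    if cfg.dropout > 0:
        counts[rng.random(counts.shape) < cfg.dropout] = 0

    # QC metadata, with deliberate violations.
    n_features = rng.integers(1200, 6800, size=n)
    pct_mito = 5.0 * rng.beta(2.0, 8.0, size=n)
    violators = np.flatnonzero(rng.random(n) < cfg.qc_violation_rate)
    kind = rng.integers(0, 3, size=violators.size)
    n_features[violators[kind == 0]] = rng.integers(
        200, 1000, size=int((kind == 0).sum())
    )
    n_features[violators[kind == 1]] = rng.integers(
        7001, 9000, size=int((kind == 1).sum())
    )
    pct_mito[violators[kind == 2]] = 5.0 + 10.0 * rng.beta(
        2.0, 5.0, size=int((kind == 2).sum())
    )

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(
            {"n_features": n_features, "pct_mito": pct_mito}, index=cell_ids
        ),
        var=pd.DataFrame(index=pd.Index(names, name="gene")),
    )
    truth = {
        "heteroplasmy": h,
        "covariate_heteroplasmy": cov_het,
        "effect_genes": {
            eg.gene: {"theta": eg.theta, "lfc": eg.lfc, "link": eg.link}
            for eg in cfg.effect_genes
        },
    }
    return allele_counts, adata, truth
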