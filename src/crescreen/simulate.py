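"""Seeded generators for every input the screen pipeline consumes.

The generators emulate a desk-scale version of a tiling CRISPRi screen of
risk cis-regulatory elements (rCREs) plus the orthogonal data types the
downstream analyses need: a PAM-dense mini-genome, day-0/day-16 guide
counts with planted depleted regions, epigenomic signal tracks correlated
with planted essentiality, and a genotype/methylation/expression cohort in
which the genotype effect on expression exists only in the
high-methylation stratum.

Every generator draws from an independent, deterministic stream derived
from the single ``SimConfig.seed``, so adding draws to one generator never
shifts another, and a fixed seed reproduces outputs byte-identically.
Ground truth (which guides were depleted, which samples sit in the high
stratum, the planted effect sizes) is returned as sidecar tables so
downstream sensitivity/FDR can be computed without touching generator
internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import inv_boxcox

# Stream ids: one per generator so streams are independent of call order.
_STREAM_GENOME = 11
_STREAM_SCREEN = 22
_STREAM_TRACK = 33
_STREAM_COHORT = 44

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the screen design being emulated: two replicates per
    timepoint, ~500 reads per guide (a stand-in for the several-hundred-cell
    per-guide representation of pooled screens), 400 bp target regions, and
    a 128-sample cohort with a common risk-allele frequency.
    """

    seed: int = 0
    genome_length: int = 20_000
    pam_rich: bool = True
    n_regions: int = 10
    region_length: int = 400
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    sequencing_depth: float = 500.0
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    abundance_sigma: float = 0.5
    signal_correlation: float = 0.6
    cohort_n: int = 128
    maf: float = 0.3
    beta_geno: float = 0.4
    noise_sd: float = 0.5
    meth_threshold: float = 0.5
    coexpression_r: float = 0.7
    n_neighbor_genes: int = 3
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.region_length < 100:
            raise ValueError("region_length must be >= 100")
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (-1 <= self.signal_correlation <= 1):
            raise ValueError("signal_correlation must lie in [-1, 1]")
        if self.sequencing_depth < 0:
            raise ValueError("sequencing_depth must be >= 0")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(config_seed)])


# ---------------------------------------------------------------------------
# mini-genome


def make_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a mini-genome and non-overlapping target regions.

    Returns ``({chrom: sequence}, regions)`` where ``regions`` is a BED-like
    frame (chrom, start, end, name). With ``pam_rich`` the region sequence is
    built from NGG triplets (N drawn from A/T/G) so a candidate protospacer
    exists at one or more positions per 3 bp on the forward strand while
    guide GC content mostly stays inside conventional efficiency bounds.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    L, n, w = config.genome_length, config.n_regions, config.region_length
    if L < n * w * 2:
        raise ValueError(
            f"cannot pack {n} regions of {w} bp into {L} bp "
            "(need genome_length >= n_regions * region_length * 2)"
        )
    seq = rng.choice(_BASES, size=L)
    slot = L // n
    starts = [i * slot + (slot - w) // 2 for i in range(n)]
    rows = []
    for i, start in enumerate(starts):
        if config.pam_rich:
            block = _pam_rich_sequence(rng, w)
            seq[start : start + w] = block
        rows.append(
            {
                "chrom": config.chrom,
                "start": start,
                "end": start + w,
                "name": f"region_{i:04d}",
            }
        )
    regions = pd.DataFrame(rows)
    return {config.chrom: "".join(seq)}, regions


def _pam_rich_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """NGG triplet tiling: a GG dinucleotide at least every 3 bp."""
    n_blocks = length // 3 + 1
    ns = rng.choice(np.array(list("ATG")), size=n_blocks)
    out = np.empty(3 * n_blocks, dtype="<U1")
    out[0::3] = ns
    out[1::3] = "G"
    out[2::3] = "G"
    return out[:length]


# ---------------------------------------------------------------------------
# screen counts


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float, size=None
) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha*mu^2; alpha=0 is Poisson."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def simulate_screen_counts(
    library, config: SimConfig
) -> tuple["CountMatrix", pd.DataFrame]:
    """Simulate day-0/day-16 guide counts with planted depletion.

    ``library`` is a guide manifest (``GuideLibrary`` or a DataFrame with at
    least ``guide_id``, ``region_id``, ``cut_site``). Day-0 counts are
    NB(depth * a_g, alpha) with lognormal per-guide abundances a_g (library
    skew); day-16 expected counts are scaled by 2**effect for guides whose
    cut site falls in a planted region. Returns the count matrix and a
    ground-truth table (guide_id, region_id, true_log2fc).
    """
    from .scoring import CountMatrix

    manifest = getattr(library, "guides", library)
    if not isinstance(manifest, pd.DataFrame):
        raise TypeError("library must be a GuideLibrary or guide DataFrame")
    unknown = set(config.planted_effects) - set(manifest["region_id"])
    if unknown:
        raise ValueError(f"planted_effects reference unknown regions: {unknown}")

    rng = _rng(config.seed, _STREAM_SCREEN)
    n_guides = len(manifest)
    sigma = config.abundance_sigma
    abundance = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_guides))
    mu0 = config.sequencing_depth * abundance
    effects = (
        manifest["region_id"].map(config.planted_effects).fillna(0.0).to_numpy()
    )
    mu16 = mu0 * np.power(2.0, effects)

    counts = {}
    meta_rows = []
    for rep in range(1, config.n_replicates + 1):
        name = f"day0_rep{rep}"
        counts[name] = _nb_draw(rng, mu0, config.nb_dispersion)
        meta_rows.append({"sample": name, "timepoint": "day0", "replicate": rep})
    for rep in range(1, config.n_replicates + 1):
        name = f"day16_rep{rep}"
        counts[name] = _nb_draw(rng, mu16, config.nb_dispersion)
        meta_rows.append({"sample": name, "timepoint": "day16", "replicate": rep})

    count_df = pd.DataFrame(counts, index=manifest["guide_id"].to_numpy())
    count_df.index.name = "guide_id"
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        {
            "guide_id": manifest["guide_id"].to_numpy(),
            "region_id": manifest["region_id"].to_numpy(),
            "true_log2fc": effects,
        }
    )
    return CountMatrix(counts=count_df, meta=meta), truth


# ---------------------------------------------------------------------------
# signal tracks


def simulate_signal_track(
    regions: pd.DataFrame,
    essentiality_z: Sequence[float],
    rho: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Piecewise-constant positive signal whose per-region maximum has
    Pearson correlation ~rho with ``essentiality_z``.

    Each region becomes three bedGraph intervals: two half-height shoulders
    flanking a central peak carrying the region's value, so maximum
    extraction is exercised non-trivially. rho = +/-1 produces a noiseless
    linear map.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    z = np.asarray(essentiality_z, dtype=float)
    if len(z) != len(regions):
        raise ValueError("essentiality_z must align with regions")
    rng = _rng(seed, _STREAM_TRACK)
    zs = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    noise = rng.standard_normal(len(z))
    latent = rho * zs + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    values = 10.0 + 2.0 * latent
    values = np.maximum(values, 1e-6)

    rows = []
    for (_, reg), v in zip(regions.iterrows(), values):
        third = (reg["end"] - reg["start"]) // 3
        a, b = reg["start"] + third, reg["end"] - third
        rows.append((reg["chrom"], reg["start"], a, round(v / 2, 6)))
        rows.append((reg["chrom"], a, b, round(v, 6)))
        rows.append((reg["chrom"], b, reg["end"], round(v / 2, 6)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a genotype/methylation/expression cohort.

    Genotype is an additive risk-allele dosage Binomial(2, maf); CpG
    methylation is a 50:50 Beta(2,8)/Beta(8,2) mixture (bimodal, as at a
    variably methylated CTCF site); latent focal-gene expression gains
    ``beta_geno`` per risk allele only when methylation exceeds
    ``meth_threshold``. One neighbor gene is co-expressed with the focal
    gene (Pearson r = ``coexpression_r``) in the high stratum only; the
    remaining neighbors are independent. Latent values are mapped through
    the inverse Box-Cox transform (lambda = -0.1) so stored expression is
    strictly positive and right-skewed, as RNA abundance is.

    Returns ``(cohort, truth)``; truth records stratum membership and the
    planted parameters.
    """
    if config.cohort_n < 20:
        raise ValueError("cohort_n must be >= 20")
    rng = _rng(config.seed, _STREAM_COHORT)
    n = config.cohort_n
    lam = -0.1

    genotype = rng.binomial(2, config.maf, size=n)
    comp = rng.random(n) < 0.5
    meth = np.where(comp, rng.beta(2, 8, size=n), rng.beta(8, 2, size=n))
    high = meth > config.meth_threshold

    eps = config.noise_sd * rng.standard_normal(n)
    latent_focal = config.beta_geno * genotype * high + eps

    genes = {"focal": latent_focal}
    neighbor_names = [f"neighbor{i + 1}" for i in range(config.n_neighbor_genes)]
    for j, gname in enumerate(neighbor_names):
        eta = rng.standard_normal(n)
        if j == 0 and high.any():
            # unit-variance mixing so the high-stratum Pearson r is exact
            r = config.coexpression_r
            mu_h = latent_focal[high].mean()
            sd_h = latent_focal[high].std() or 1.0
            zf = (latent_focal - mu_h) / sd_h
            coreg = r * zf + np.sqrt(max(0.0, 1 - r**2)) * eta
            genes[gname] = np.where(high, coreg, config.noise_sd * eta)
        else:
            genes[gname] = config.noise_sd * eta

    cohort = pd.DataFrame({"sample_id": [f"S{i:03d}" for i in range(n)]})
    cohort["genotype"] = genotype
    cohort["meth"] = np.round(meth, 6)
    for gname, latent in genes.items():
        # keep 1 + lam*y > 0 so the inverse transform stays finite/positive
        safe = np.clip(latent, None, (1.0 - 1e-6) / -lam)
        cohort[gname] = np.round(inv_boxcox(safe, lam), 6)

    truth = {
        "beta_geno": config.beta_geno,
        "meth_threshold": config.meth_threshold,
        "high_stratum": pd.Series(high, index=cohort["sample_id"], name="high"),
        "coexpressed_gene": neighbor_names[0] if neighbor_names else None,
        "coexpression_r": config.coexpression_r,
        "boxcox_lambda": lam,
    }
    return cohort, truth
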