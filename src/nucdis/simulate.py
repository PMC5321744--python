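"""Synthetic cohorts with known nucleosome-turnover ground truth.

The generator inverts the inference model: it draws per-gene wild-type
transcription levels, couples disassembly to transcription with
multiplicative noise, splits disassembly into loss and reassembly through a
per-gene Beta-distributed reassembly fraction rho, applies the genotype
effects (remodeller deletion scales disassembly and loss by 1 - x'; the
reassembly-null FACT mutant sets R = 0), and finally emits noisy gene-level
observables plus coverage tracks and a gene annotation so every pipeline
stage can run without external data.

Draw order under the single seeded stream (documented so partial
regeneration stays reproducible): (1) log2 transcription P, (2) disassembly
coupling noise, (3) reassembly fractions rho, (4) observable noises in
the order dH3_fft3, dH3_spt16, pol, dpol_fft3, exchange, (5) annotation
layout (gene lengths, intergenic gaps, strands).

Per-gene reassembly heterogeneity (finite Beta shapes) is what makes x'
identifiable downstream: a constant rho makes loss exactly proportional to
disassembly and the correlation curve flat.  ``constant_rho=True`` selects
that degenerate regime deliberately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .occupancy import (
    CoverageTrack,
    GeneOccupancyTable,
    _deposit,
    write_coverage_bedgraph,
    write_gene_annotation_gff3,
    write_gene_table,
)

GENE_TABLE_COLUMNS = ["pol_wt", "dH3_fft3", "dH3_spt16", "dpol_fft3", "exchange"]

#: mean and sd of log gene-body length (bp) and the intergenic gap range,
#: yeast-scale defaults
_GENE_LEN_LOG_MEAN = math.log(1400.0)
_GENE_LEN_LOG_SD = 0.4
_GENE_LEN_MIN = 300
_GAP_RANGE = (200, 1000)
_TRAILING_PAD = 600


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    x_prime_true is the remodeller's true relative contribution to
    transcription-coupled disassembly; beta scales disassembly in the
    reassembly-null genotype; d_median / d_max calibrate the wild-type
    disassembly fractions; rho_alpha / rho_beta shape the per-gene
    reassembly fraction; the sigma_* parameters are the noise scales of the
    latent coupling and of each observable.
    """

    n_genes: int = 5000
    seed: int = 0
    x_prime_true: float = 0.84
    beta: float = 1.0
    d_median: float = 0.10
    d_max: float = 0.90
    rho_alpha: float = 8.0
    rho_beta: float = 2.0
    constant_rho: bool = False
    sigma_T: float = 1.2
    sigma_D: float = 0.3
    sigma_obs: float = 0.01
    sigma_P: float = 0.2
    sigma_E: float = 0.4
    gamma: float = 1.0
    track_bin_bp: int = 10
    n_chromosomes: int = 2

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError(f"n_genes must be >= 2, got {self.n_genes}")
        if not 0.0 < self.x_prime_true <= 1.0:
            raise ConfigError(f"x_prime_true must be in (0, 1], got {self.x_prime_true}")
        if not 0.0 < self.d_median < self.d_max <= 1.0:
            raise ConfigError(
                f"need 0 < d_median < d_max <= 1, got d_median={self.d_median}, d_max={self.d_max}"
            )
        if self.beta <= 0 or self.beta * self.d_max > 1.0:
            raise ConfigError(
                f"beta must satisfy 0 < beta <= 1/d_max, got beta={self.beta}"
            )
        for name in ("rho_alpha", "rho_beta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("sigma_T", "sigma_D", "sigma_obs", "sigma_P", "sigma_E"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.track_bin_bp <= 0:
            raise ConfigError(f"track_bin_bp must be positive, got {self.track_bin_bp}")
        if self.n_chromosomes < 1:
            raise ConfigError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")


@dataclass
class SyntheticTruth:
    """Latent per-gene turnover fractions per genotype plus the scalars."""

    gene_ids: np.ndarray
    transcription: np.ndarray       # linear T_g = 2**P_g
    log2_pol: np.ndarray            # P_g, noise-free log2 RNAPII occupancy
    rho: np.ndarray                 # WT reassembly fraction of disassembled nucleosomes
    d_wt: np.ndarray
    l_wt: np.ndarray
    r_wt: np.ndarray
    d_fft3: np.ndarray
    l_fft3: np.ndarray
    r_fft3: np.ndarray
    d_spt16: np.ndarray
    l_spt16: np.ndarray
    r_spt16: np.ndarray
    x_prime_true: float
    beta: float

    def validate(self) -> None:
        for geno in ("wt", "fft3", "spt16"):
            d = getattr(self, f"d_{geno}")
            l = getattr(self, f"l_{geno}")
            r = getattr(self, f"r_{geno}")
            if not np.allclose(d, l + r, rtol=0, atol=1e-12):
                raise ValidationError(f"{geno}: D != L + R")
            if (l < 0).any() or (r < 0).any() or (d > 1).any():
                raise ValidationError(f"{geno}: fractions outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "transcription": self.transcription, "log2_pol": self.log2_pol, "rho": self.rho,
            "d_wt": self.d_wt, "l_wt": self.l_wt, "r_wt": self.r_wt,
            "d_fft3": self.d_fft3, "l_fft3": self.l_fft3, "r_fft3": self.r_fft3,
            "d_spt16": self.d_spt16, "l_spt16": self.l_spt16, "r_spt16": self.r_spt16,
        }
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene_id"))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "x_prime_true": self.x_prime_true,
            "beta": self.beta,
            "genes": self.to_frame().reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")


@dataclass
class SyntheticCohort:
    """Annotation, coverage tracks, gene-level observables and the truth."""

    annotation: pd.DataFrame
    tracks: dict[str, CoverageTrack] | None
    gene_table: GeneOccupancyTable
    truth: SyntheticTruth
    config: GeneratorConfig

    def chrom_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for row in self.annotation.itertuples(index=False):
            pad = -(-(row.end + _TRAILING_PAD) // self.config.track_bin_bp)
            sizes[row.chrom] = max(
                sizes.get(row.chrom, 0), pad * self.config.track_bin_bp
            )
        return sizes


def generate_cohort(config: GeneratorConfig, tracks: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"gene_{i:05d}" for i in range(n)])

    # (1)-(3) latent state
    log2_pol = rng.normal(0.0, config.sigma_T, n)
    transcription = 2.0 ** log2_pol
    coupling_noise = np.exp(rng.normal(0.0, config.sigma_D, n))
    raw_d = transcription * coupling_noise
    kappa = config.d_median / float(np.median(raw_d))
    d_wt = np.minimum(kappa * raw_d, config.d_max)
    if config.constant_rho:
        rho = np.full(n, config.rho_alpha / (config.rho_alpha + config.rho_beta))
        _ = rng.beta(config.rho_alpha, config.rho_beta, n)  # keep stream alignment
    else:
        rho = rng.beta(config.rho_alpha, config.rho_beta, n)
    # split first, then define D := L + R so conservation is float-exact
    l_wt = (1.0 - rho) * d_wt
    r_wt = rho * d_wt
    d_wt = l_wt + r_wt

    xp = config.x_prime_true
    l_fft3 = (1.0 - xp) * l_wt
    r_fft3 = (1.0 - xp) * r_wt
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        transcription=transcription,
        log2_pol=log2_pol,
        rho=rho,
        d_wt=d_wt, l_wt=l_wt, r_wt=r_wt,
        d_fft3=l_fft3 + r_fft3,
        l_fft3=l_fft3,
        r_fft3=r_fft3,
        d_spt16=config.beta * d_wt,
        l_spt16=config.beta * d_wt,
        r_spt16=np.zeros(n),
        x_prime_true=xp,
        beta=config.beta,
    )
    truth.validate()

    # (4) observables
    dh3_fft3 = xp * l_wt + rng.normal(0.0, config.sigma_obs, n)
    dh3_spt16 = (l_wt - config.beta * d_wt) + rng.normal(0.0, config.sigma_obs, n)
    pol_obs = log2_pol + rng.normal(0.0, config.sigma_P, n)
    dpol_fft3 = -config.gamma * xp * d_wt + rng.normal(0.0, config.sigma_obs, n)
    exchange = l_wt * np.exp(rng.normal(0.0, config.sigma_E, n))
    gene_table = GeneOccupancyTable(
        values=pd.DataFrame(
            {
                "pol_wt": pol_obs,
                "dH3_fft3": dh3_fft3,
                "dH3_spt16": dh3_spt16,
                "dpol_fft3": dpol_fft3,
                "exchange": exchange,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        tags={
            "pol_wt": "log2_ip_over_input",
            "dH3_fft3": "linear",
            "dH3_spt16": "linear",
            "dpol_fft3": "linear",
            "exchange": "linear",
        },
    )

    # (5) annotation layout; coordinates snapped to the coverage bin grid so
    # rasterized gene bodies are exact (no baseline bleed into edge bins)
    bp = config.track_bin_bp

    def snap(values, minimum):
        return np.maximum(minimum, np.round(values / bp).astype(int) * bp)

    min_len = -(-_GENE_LEN_MIN // bp) * bp
    lengths = snap(rng.lognormal(_GENE_LEN_LOG_MEAN, _GENE_LEN_LOG_SD, n), min_len)
    gaps = snap(rng.integers(_GAP_RANGE[0], _GAP_RANGE[1] + 1, n).astype(float), bp)
    strands = rng.choice(np.array(["+", "-"]), n)
    chrom_of = np.array_split(np.arange(n), config.n_chromosomes)
    records = []
    for ci, idx in enumerate(chrom_of):
        pos = 0
        chrom = f"chr{ci + 1}"
        for g in idx:
            start = pos + int(gaps[g])
            end = start + int(lengths[g])
            records.append((gene_ids[g], chrom, start, end, strands[g]))
            pos = end
    annotation = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand"]
    )

    cohort = SyntheticCohort(
        annotation=annotation, tracks=None, gene_table=gene_table,
        truth=truth, config=config,
    )
    if tracks:
        cohort.tracks = generate_tracks(cohort, config)
    return cohort


def generate_tracks(
    cohort: SyntheticCohort, config: GeneratorConfig
) -> dict[str, CoverageTrack]:
    """Coverage tracks at ``track_bin_bp`` resolution.

    The IP signal over each gene body is the gene-level target value with a
    flat (unit-mean) shape; the intergenic baseline and the control track
    are flat 1.0.  Bin values at gene edges are exact length-weighted
    averages, so gene-level means recover the targets.
    """
    truth = cohort.truth
    gene_value = {
        "control": None,  # flat 1.0
        "pol_wt": truth.transcription,
        "h3_wt": 1.0 - truth.l_wt,
        "h3_fft3": 1.0 - truth.l_fft3,
        "h3_spt16": 1.0 - truth.l_spt16,
    }
    order = {gid: i for i, gid in enumerate(truth.gene_ids)}
    sizes = cohort.chrom_sizes()
    step = config.track_bin_bp
    tracks: dict[str, CoverageTrack] = {}
    for sample, values in gene_value.items():
        data: dict[str, np.ndarray] = {}
        for chrom, size in sizes.items():
            mass = np.full(size // step, float(step))  # baseline 1.0 per bp
            if values is not None:
                sub = cohort.annotation[cohort.annotation["chrom"] == chrom]
                for row in sub.itertuples(index=False):
                    v = float(values[order[row.gene_id]])
                    _deposit(mass, step, int(row.start), int(row.end), v - 1.0)
            data[chrom] = mass / step
        tracks[sample] = CoverageTrack(step_bp=step, data=data)
    return tracks


def truth_summary(truth: SyntheticTruth) -> dict:
    """Per-genotype turnover means plus the calibration scalars."""
    out: dict = {"x_prime_true": truth.x_prime_true, "beta": truth.beta}
    for geno in ("wt", "fft3", "spt16"):
        for part in ("d", "l", "r"):
            out[f"mean_{part}_{geno}"] = float(getattr(truth, f"{part}_{geno}").mean())
    out["median_d_wt"] = float(np.median(truth.d_wt))
    return out


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write annotation (GFF3), tracks (bedGraph), gene table (TSV),
    chrom sizes and truth (JSON); returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["annotation"] = outdir / "annotation.gff3"
    write_gene_annotation_gff3(cohort.annotation, paths["annotation"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in cohort.chrom_sizes().items():
            fh.write(f"{chrom}\t{size}\n")
    paths["gene_table"] = outdir / "gene_table.tsv"
    write_gene_table(cohort.gene_table, paths["gene_table"])
    paths["truth"] = outdir / "truth.json"
    cohort.truth.to_json(paths["truth"])
    if cohort.tracks:
        track_dir = outdir / "tracks"
        track_dir.mkdir(exist_ok=True)
        for sample, track in cohort.tracks.items():
            p = track_dir / f"{sample}.bedgraph"
            write_coverage_bedgraph(track, p)
            paths[f"track_{sample}"] = p
    return paths
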