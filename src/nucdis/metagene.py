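"""Scale-regions metagene matrices and mean profiles.

Each gene contributes one matrix row laid out 5'->3': fixed-width upstream
flank bins, the gene body resampled to a fixed number of bins by
length-weighted averaging, then fixed-width downstream flank bins.  Rows of
minus-strand genes are computed in genomic order and reversed, so the
leftmost columns are always the promoter side.  Gene bodies shorter than
one track bin are still resampled (from the single overlapping bin); flanks
running past a chromosome end follow the configured missing policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .occupancy import CoverageTrack, interval_mean

logger = logging.getLogger(__name__)


@dataclass
class MetageneConfig:
    """Scale-regions layout: flank widths, body bin count, flank bin width."""

    upstream_bp: int = 500
    downstream_bp: int = 500
    body_bins: int = 60
    flank_bin_bp: int = 10
    missing_policy: str = "zero"  # or "drop"

    def __post_init__(self) -> None:
        if self.body_bins < 1:
            raise ConfigError(f"body_bins must be >= 1, got {self.body_bins}")
        if self.flank_bin_bp <= 0:
            raise ConfigError(f"flank_bin_bp must be positive, got {self.flank_bin_bp}")
        for name in ("upstream_bp", "downstream_bp"):
            value = getattr(self, name)
            if value < 0 or value % self.flank_bin_bp:
                raise ConfigError(
                    f"{name}={value} must be a non-negative multiple of flank_bin_bp"
                )
        if self.missing_policy not in ("zero", "drop"):
            raise ConfigError(f"missing_policy must be 'zero' or 'drop'")

    @property
    def n_upstream(self) -> int:
        return self.upstream_bp // self.flank_bin_bp

    @property
    def n_downstream(self) -> int:
        return self.downstream_bp // self.flank_bin_bp

    @property
    def n_columns(self) -> int:
        return self.n_upstream + self.body_bins + self.n_downstream


@dataclass
class MetageneMatrix:
    """Genes x bins matrix with TSS/TES anchor column indices.

    ``tss_index`` is the first body column; ``tes_index`` is the first
    downstream column (one past the last body column).
    """

    values: pd.DataFrame
    tss_index: int
    tes_index: int
    dropped: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def _gene_row(
    values: np.ndarray, step: int, start: int, end: int, strand: str,
    config: MetageneConfig, oob: str,
) -> np.ndarray:
    # genomic left-to-right; for '-' the left flank is the downstream side
    left_bp = config.upstream_bp if strand == "+" else config.downstream_bp
    right_bp = config.downstream_bp if strand == "+" else config.upstream_bp
    n_left = left_bp // config.flank_bin_bp
    n_right = right_bp // config.flank_bin_bp
    row = np.empty(n_left + config.body_bins + n_right)
    fb = config.flank_bin_bp
    for j in range(n_left):
        a = start - left_bp + j * fb
        row[j] = interval_mean(values, step, a, a + fb, oob=oob)
    body_len = end - start
    for j in range(config.body_bins):
        a = start + body_len * j / config.body_bins
        b = start + body_len * (j + 1) / config.body_bins
        row[n_left + j] = interval_mean(values, step, a, b, oob=oob)
    for j in range(n_right):
        a = end + j * fb
        row[n_left + config.body_bins + j] = interval_mean(values, step, a, a + fb, oob=oob)
    return row[::-1] if strand == "-" else row


def scale_regions_matrix(
    track: CoverageTrack,
    genes: pd.DataFrame,
    config: MetageneConfig | None = None,
) -> MetageneMatrix:
    """Build the genes x (upstream + body + downstream) metagene matrix.

    Every gene weighs equally (one row); body values are exact
    length-weighted means over fractional bin boundaries, so a constant
    track yields a constant matrix for any layout.
    """
    config = config or MetageneConfig()
    oob = "zero" if config.missing_policy == "zero" else "nan"
    rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for rec in genes.itertuples(index=False):
        if rec.chrom not in track.data:
            dropped.append(rec.gene_id)
            continue
        row = _gene_row(
            track.data[rec.chrom], track.step_bp,
            int(rec.start), int(rec.end), rec.strand, config, oob,
        )
        if config.missing_policy == "drop" and np.isnan(row).any():
            dropped.append(rec.gene_id)
            continue
        rows[rec.gene_id] = row
    if dropped:
        logger.info("metagene: dropped %d genes (missing coverage)", len(dropped))
    labels = (
        [f"u{j}" for j in range(config.n_upstream)]
        + [f"b{j}" for j in range(config.body_bins)]
        + [f"d{j}" for j in range(config.n_downstream)]
    )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels, dtype=float)
    if not rows:
        df = pd.DataFrame(np.empty((0, config.n_columns)), columns=labels)
    return MetageneMatrix(
        values=df,
        tss_index=config.n_upstream,
        tes_index=config.n_upstream + config.body_bins,
        dropped=dropped,
    )


def mean_profile(matrix: MetageneMatrix, gene_set=None) -> np.ndarray:
    """Column-wise NaN-aware mean over a gene selection (default: all rows)."""
    if gene_set is None:
        sub = matrix.values
    else:
        wanted = pd.Index(sorted(gene_set))
        present = wanted.intersection(matrix.gene_ids)
        missing = len(wanted) - len(present)
        if missing:
            logger.info("mean_profile: %d requested genes absent from matrix", missing)
        sub = matrix.values.loc[present]
    if sub.shape[0] == 0:
        raise ValidationError("mean_profile: empty gene selection")
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub.to_numpy(), axis=0)


def write_matrix_tsv(matrix: MetageneMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_profile_tsv(profile: np.ndarray, matrix: MetageneMatrix, path: str | Path) -> None:
    pd.DataFrame({"bin": matrix.values.columns, "mean_signal": profile}).to_csv(
        path, sep="\t", index=False
    )


def plot_profile(profile: np.ndarray, matrix: MetageneMatrix, path: str | Path,
                 title: str = "metagene profile") -> None:
    """Line plot of a mean profile with TSS/TES markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(np.arange(len(profile)), profile, lw=1.5)
    for x, label in ((matrix.tss_index, "TSS"), (matrix.tes_index, "TES")):
        ax.axvline(x, color="grey", ls="--", lw=0.8)
        ax.annotate(label, (x, ax.get_ylim()[1]), ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("bin (5' -> 3')")
    ax.set_ylabel("mean signal")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
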