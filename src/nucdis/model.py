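"""Steady-state D = L + R decomposition of transcription-coupled
nucleosome turnover and the grid-search contribution estimator.

Model
-----
At steady state the fraction of gene-body nucleosomes disassembled by
transcribing RNAPII (D) splits into nucleosomes lost (L, not immediately
reassembled, visible as reduced histone H3 occupancy) and nucleosomes
transiently disassembled but immediately reassembled (R):

    D = L + R.

Deleting the remodeller (fft3-null) reduces disassembly and loss by the
same factor, L_fft3 = (1 - x') * L_wt, where x' in (0, 1] is the
remodeller's relative contribution to disassembly, so the observed H3
occupancy gain is dH3_fft3 = x' * L_wt.  In the reassembly-null FACT
mutant (spt16-18) R ~ 0, hence D_spt16 = L_spt16 and the observed change is
dH3_spt16 = L_wt - D_spt16.  Eliminating L_wt:

    D_spt16(x') = dH3_fft3 / x' - dH3_spt16.

Since disassembly is transcription-coupled, x' is estimated as the grid
point maximizing the Pearson correlation between D_spt16(x') and RNAPII
occupancy.  The per-gene disassembly estimates are on an arbitrary scale
(proportional to x' * D_wt); only correlations with them are meaningful.

x' is identifiable only because loss is not strictly proportional to
disassembly (per-gene reassembly efficiency varies): if L were exactly
proportional to D, the reconstruction would be an affine function of D at
every x' and the correlation curve would be flat.  A flatness check
(max r - min r below ``flatness_tol``) flags that failure mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .occupancy import GeneOccupancyTable

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = 0.01
DEFAULT_FLATNESS_TOL = 1e-3


def default_grid(step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """The x' grid over (0, 1]: {step, 2*step, ..., 1}."""
    n = int(round(1.0 / step))
    return np.round(np.arange(1, n + 1) * step, 12)


@dataclass
class DisassemblyObservables:
    """Per-gene observables feeding the estimator.

    dh3_fft3 and dh3_spt16 are H3 occupancy changes (mutant relative to WT)
    on any single consistent scale; pol is WT RNAPII occupancy (log2
    IP/INPUT or any monotone transcription proxy).  Genes with a missing
    value in any vector are removed once at construction, so every grid
    point sees the same universe.
    """

    gene_ids: np.ndarray
    dh3_fft3: np.ndarray
    dh3_spt16: np.ndarray
    pol: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        for name in ("dh3_fft3", "dh3_spt16", "pol"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != self.gene_ids.shape:
                raise ValidationError(f"{name}: length mismatch with gene_ids")
            setattr(self, name, v)
        keep = (
            np.isfinite(self.dh3_fft3)
            & np.isfinite(self.dh3_spt16)
            & np.isfinite(self.pol)
        )
        self.n_dropped += int((~keep).sum())
        if self.n_dropped:
            logger.info("observables: dropped %d genes with missing values", self.n_dropped)
        self.gene_ids = self.gene_ids[keep]
        self.dh3_fft3 = self.dh3_fft3[keep]
        self.dh3_spt16 = self.dh3_spt16[keep]
        self.pol = self.pol[keep]

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_table(
        cls,
        table: GeneOccupancyTable | pd.DataFrame,
        dh3_fft3: str = "dH3_fft3",
        dh3_spt16: str = "dH3_spt16",
        pol: str = "pol_wt",
    ) -> "DisassemblyObservables":
        df = table.values if isinstance(table, GeneOccupancyTable) else table
        missing = [c for c in (dh3_fft3, dh3_spt16, pol) if c not in df.columns]
        if missing:
            raise ValidationError(f"gene table lacks columns {missing}")
        return cls(
            gene_ids=df.index.to_numpy(),
            dh3_fft3=df[dh3_fft3].to_numpy(dtype=float),
            dh3_spt16=df[dh3_spt16].to_numpy(dtype=float),
            pol=df[pol].to_numpy(dtype=float),
        )


@dataclass
class ContributionEstimate:
    """Result of the x' grid search.

    ``d_estimates`` is the per-gene reconstructed disassembly at ``x_hat``
    on an arbitrary scale; ``identifiable`` is False when the correlation
    curve is flat to within ``flatness_tol`` (loss proportional to
    disassembly, x' unrecoverable).
    """

    grid: np.ndarray
    r_curve: np.ndarray
    x_hat: float
    r_max: float
    flatness: float
    identifiable: bool
    d_estimates: np.ndarray
    gene_ids: np.ndarray
    n_genes_used: int
    flatness_tol: float = DEFAULT_FLATNESS_TOL

    def to_dict(self) -> dict:
        return {
            "x_hat": self.x_hat,
            "r_max": self.r_max,
            "flatness": self.flatness,
            "identifiable": self.identifiable,
            "flatness_tol": self.flatness_tol,
            "n_genes_used": self.n_genes_used,
            "grid": [float(v) for v in self.grid],
            "r_curve": [float(v) for v in self.r_curve],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def d_estimates_series(self) -> pd.Series:
        return pd.Series(self.d_estimates, index=self.gene_ids, name="d_estimate")


def reconstruct_disassembly(
    obs: DisassemblyObservables, x_prime: float
) -> np.ndarray:
    """Per-gene reassembly-null disassembly D_spt16 at a candidate x'.

    Returns ``dh3_fft3 / x' - dh3_spt16``.  The positively rescaled form
    ``dh3_fft3 - x' * dh3_spt16`` differs only by the factor x' > 0 and is
    interchangeable wherever only correlations are consumed.
    """
    if not 0.0 < x_prime <= 1.0:
        raise ValidationError(f"x_prime must lie in (0, 1], got {x_prime}")
    return obs.dh3_fft3 / x_prime - obs.dh3_spt16


def _check_nondegenerate(obs: DisassemblyObservables) -> None:
    if len(obs) < 3:
        raise ValidationError(f"need >= 3 complete gene observations, got {len(obs)}")
    if np.ptp(obs.pol) == 0:
        raise ValidationError("RNAPII occupancy has zero variance")
    if np.ptp(obs.dh3_fft3) == 0 and np.ptp(obs.dh3_spt16) == 0:
        raise ValidationError("both H3 change vectors have zero variance")


def contribution_curve(
    obs: DisassemblyObservables, grid: np.ndarray | None = None
) -> np.ndarray:
    """Pearson r between reconstructed disassembly and RNAPII occupancy at
    every grid point, on one fixed gene universe."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or grid.min() <= 0 or grid.max() > 1:
        raise ValidationError("grid must be non-empty within (0, 1]")
    _check_nondegenerate(obs)
    # vectorized: rows of recon are D(x') across genes
    recon = obs.dh3_fft3[None, :] / grid[:, None] - obs.dh3_spt16[None, :]
    recon = recon - recon.mean(axis=1, keepdims=True)
    pol = obs.pol - obs.pol.mean()
    num = recon @ pol
    denom = np.sqrt((recon**2).sum(axis=1) * (pol**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return r


def estimate_contribution(
    obs: DisassemblyObservables,
    grid: np.ndarray | None = None,
    flatness_tol: float = DEFAULT_FLATNESS_TOL,
) -> ContributionEstimate:
    """Grid-search estimate of the remodeller contribution x'.

    x_hat is the argmax of the correlation curve (ties broken toward the
    smallest x', i.e. the conservative contribution).  A curve flat to
    within ``flatness_tol`` is returned flagged non-identifiable, not as an
    error.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    r_curve = contribution_curve(obs, grid)
    finite = np.isfinite(r_curve)
    if not finite.any():
        raise ValidationError("correlation undefined at every grid point")
    r_max = float(np.nanmax(r_curve))
    best = int(np.flatnonzero(finite & (r_curve == r_max))[0])  # first = smallest x'
    flatness = float(np.nanmax(r_curve) - np.nanmin(r_curve))
    x_hat = float(grid[best])
    return ContributionEstimate(
        grid=grid,
        r_curve=r_curve,
        x_hat=x_hat,
        r_max=r_max,
        flatness=flatness,
        identifiable=bool(flatness >= flatness_tol),
        d_estimates=reconstruct_disassembly(obs, x_hat),
        gene_ids=obs.gene_ids.copy(),
        n_genes_used=len(obs),
        flatness_tol=flatness_tol,
    )


def fun30_disassembly_levels(estimate: ContributionEstimate) -> pd.Series:
    """Per-gene remodeller-mediated disassembly levels (arbitrary scale).

    Under the model these are proportional to x' * D_wt, suitable only for
    correlation against occupancy or occupancy-change columns.
    """
    if not estimate.identifiable:
        logger.warning(
            "fun30_disassembly_levels: estimate flagged non-identifiable "
            "(flatness %.2e < tol %.2e); levels are unreliable",
            estimate.flatness, estimate.flatness_tol,
        )
    return pd.Series(
        estimate.d_estimates, index=estimate.gene_ids, name="fun30_disassembly"
    )


def plot_contribution_curve(
    estimate: ContributionEstimate, path: str | Path
) -> None:
    """r-vs-x' curve with the argmax marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(estimate.grid, estimate.r_curve, lw=1.5)
    ax.axvline(estimate.x_hat, color="crimson", ls="--", lw=1)
    ax.annotate(
        f"x' = {estimate.x_hat:.2f}\nr = {estimate.r_max:.3f}",
        (estimate.x_hat, estimate.r_max),
        textcoords="offset points", xytext=(8, -18), fontsize=9,
    )
    ax.set_xlabel("candidate contribution x'")
    ax.set_ylabel("Pearson r vs RNAPII occupancy")
    ax.set_title("contribution grid search" + ("" if estimate.identifiable else " (flat: non-identifiable)"))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
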