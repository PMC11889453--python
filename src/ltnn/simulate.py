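"""Seeded generator of branching differentiation datasets with known truth.

Cells sit on a latent time in [0, 1]; a trunk splits into branches at a
branch point (default 0.5).  Each gene follows a smooth program of latent
time — predominantly activating sigmoids, with some deactivating sigmoids
and transient Gaussian bumps — that becomes branch-specific after the
split.  Counts are negative-binomial around a depth-scaled, per-cell
normalized program, with a fixed fraction of time-independent
mitochondrially named genes.  Because differentiation is modeled as the
progressive activation of lineage programs, the number of detected genes
per cell rises along latent time, which gives the orientation rule a
realistic diversity gradient to key on.

The generator also produces a noisy "velocity-like" training latent time,
standing in for the RNA-velocity latent time a dynamical model would
provide on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellMatrix, ValidationError, make_mito_mask
from .metrics import MilestoneNetwork


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated dataset."""

    true_time: np.ndarray        # in [0, 1]
    branch: np.ndarray           # branch index per cell (fate, also pre-split)
    milestone: np.ndarray        # per-cell milestone label
    network: MilestoneNetwork    # true transitions (directed tree)
    terminal_mask: np.ndarray    # cells in the terminal segment of a branch
    params: dict = field(default_factory=dict)

    def subset(self, keep: np.ndarray) -> "SyntheticTruth":
        keep = np.asarray(keep)
        return SyntheticTruth(
            true_time=self.true_time[keep],
            branch=self.branch[keep],
            milestone=self.milestone[keep],
            network=self.network,
            terminal_mask=self.terminal_mask[keep],
            params=self.params,
        )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_trajectory(
    n_cells: int = 1000,
    n_genes: int = 500,
    n_branches: int = 2,
    depth: float = 5000.0,
    dispersion: float = 10.0,
    mito_gene_frac: float = 0.05,
    program_noise: float = 0.1,
    branch_point: float = 0.5,
    seed: int = 0,
) -> tuple[CellMatrix, SyntheticTruth]:
    """Simulate a branching differentiation count matrix with known truth.

    Parameters
    ----------
    depth
        Expected total counts per cell (library size).
    dispersion
        Negative-binomial size parameter; ``np.inf`` switches to Poisson.
    program_noise
        Standard deviation of per-cell-per-gene lognormal program noise.
    """
    if n_cells < 100:
        raise ValidationError(f"n_cells must be >= 100; got {n_cells}")
    if n_genes < 100:
        raise ValidationError(f"n_genes must be >= 100; got {n_genes}")
    if n_branches < 1:
        raise ValidationError(f"n_branches must be >= 1; got {n_branches}")
    if not 0 < branch_point < 1:
        raise ValidationError("branch_point must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    tau = branch_point
    t = rng.uniform(0.0, 1.0, n_cells)
    branch = rng.integers(0, n_branches, n_cells)

    # milestones: shared trunk, then one label per branch.  Annotation
    # follows the expressed phenotype: branch programs activate over
    # (tau, tau + 0.2), so the milestone label switches only once the
    # lineage markers are on
    tau_commit = min(tau + 0.2, 0.5 * (1.0 + tau))
    if n_branches == 1:
        milestone = np.where(t < tau_commit, "early", "late").astype(object)
        network = MilestoneNetwork.from_edge_list([("early", "late", 1.0)])
    else:
        milestone = np.empty(n_cells, dtype=object)
        milestone[t < tau_commit] = "early"
        for b in range(n_branches):
            milestone[(t >= tau_commit) & (branch == b)] = f"branch{b}"
        network = MilestoneNetwork.from_edge_list(
            [("early", f"branch{b}", 1.0) for b in range(n_branches)]
        )
    # terminal = final half of the post-split segment of each branch
    terminal_cut = tau + 0.5 * (1.0 - tau)
    terminal = t >= terminal_cut

    # ---- gene programs ------------------------------------------------
    # Program genes carry a near-zero floor so they are effectively silent
    # until their program activates; a housekeeping block is always on.
    # With activating sigmoids dominating, the number of detected genes
    # rises along latent time (the diversity gradient the orientation rule
    # keys on).
    n_mito = max(1, int(round(mito_gene_frac * n_genes)))
    n_expr = n_genes - n_mito
    n_marker = 20  # strong markers per branch
    n_strong = n_marker * n_branches + 10  # guaranteed markers + trunk

    amp = rng.lognormal(mean=1.0, sigma=0.6, size=n_expr)            # effect
    kind = rng.choice(
        ["house", "sig_up", "sig_down", "bump"],
        size=n_expr,
        p=[0.2, 0.5, 0.1, 0.2],
    )
    base = np.where(kind == "house", rng.lognormal(0.0, 0.5, n_expr), 0.01)
    center = rng.uniform(0.1, 0.9, n_expr)
    steep = rng.uniform(5.0, 15.0, n_expr)
    width = rng.uniform(0.05, 0.2, n_expr)
    # most program genes are branch-specific after the split
    gene_branch = np.where(
        rng.random(n_expr) < 0.7, rng.integers(0, n_branches, n_expr), -1
    )
    gene_branch[kind == "house"] = -1

    # overwrite the leading genes with strong guaranteed markers; branch
    # markers switch on right after the split so lineage commitment is
    # transcriptionally sharp
    for b in range(n_branches):
        sl = slice(n_marker * b, n_marker * (b + 1))
        kind[sl] = "sig_up"
        base[sl] = 0.01
        center[sl] = rng.uniform(tau + 0.03, tau + 0.2, n_marker)
        steep[sl] = rng.uniform(15.0, 25.0, n_marker)
        amp[sl] = rng.lognormal(mean=2.5, sigma=0.3, size=n_marker)
        gene_branch[sl] = b
    sl = slice(n_marker * n_branches, n_strong)
    kind[sl] = "sig_down"
    base[sl] = 0.01
    center[sl] = rng.uniform(0.1, tau, 10)
    steep[sl] = rng.uniform(10.0, 15.0, 10)
    amp[sl] = rng.lognormal(mean=2.0, sigma=0.3, size=10)
    gene_branch[sl] = -1

    # evaluation time per cell-gene: branch-specific genes on a foreign
    # branch stay frozen at the split
    t_eval = np.tile(t[:, None], (1, n_expr))
    foreign = (gene_branch[None, :] >= 0) & (
        gene_branch[None, :] != branch[:, None]
    ) & (t[:, None] >= tau)
    t_eval[foreign] = tau

    prog = np.zeros((n_cells, n_expr))  # housekeeping genes stay at base
    up = kind == "sig_up"
    down = kind == "sig_down"
    bump = kind == "bump"
    prog[:, up] = _sigmoid(steep[up] * (t_eval[:, up] - center[up]))
    prog[:, down] = _sigmoid(-steep[down] * (t_eval[:, down] - center[down]))
    prog[:, bump] = np.exp(
        -((t_eval[:, bump] - center[bump]) ** 2) / (2 * width[bump] ** 2)
    )
    intensity = base[None, :] + amp[None, :] * prog
    if program_noise > 0:
        intensity = intensity * np.exp(
            rng.normal(0.0, program_noise, intensity.shape)
        )

    mito_level = rng.lognormal(mean=0.5, sigma=0.3, size=n_mito)
    full = np.concatenate(
        [intensity, np.tile(mito_level, (n_cells, 1))], axis=1
    )
    mu = depth * full / full.sum(axis=1, keepdims=True)

    if np.isinf(dispersion):
        counts = rng.poisson(mu)
    else:
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p)

    gene_ids = np.array(
        [f"G{i:04d}" for i in range(n_expr)]
        + [f"MT-{i:03d}" for i in range(n_mito)],
        dtype=object,
    )
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "true_time": t,
            "branch": branch,
            "milestone": milestone.astype(str),
            "terminal": terminal,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = CellMatrix(
        counts=counts.astype(np.int64),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        mito_mask=make_mito_mask(gene_ids),
        cell_meta=meta,
    )
    truth = SyntheticTruth(
        true_time=t,
        branch=branch,
        milestone=milestone,
        network=network,
        terminal_mask=terminal,
        params=dict(
            n_cells=n_cells,
            n_genes=n_genes,
            n_branches=n_branches,
            depth=depth,
            dispersion=dispersion,
            mito_gene_frac=mito_gene_frac,
            program_noise=program_noise,
            branch_point=branch_point,
            seed=seed,
        ),
    )
    return matrix, truth


def simulate_training_time(
    truth: SyntheticTruth, noise_sd: float = 0.05, seed: int = 0
) -> np.ndarray:
    """Noisy stand-in for a velocity-derived training latent time:
    true time plus Gaussian noise, clipped to [0, 1]."""
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0; got {noise_sd}")
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        return truth.true_time.copy()
    return np.clip(
        truth.true_time + rng.normal(0.0, noise_sd, truth.true_time.shape),
        0.0,
        1.0,
    )
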