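"""Kenyon-cell expansion-coding rate model and observed wiring statistics.

The mushroom body expands ~N = 58 olfactory input channels (antennal-lobe
glomeruli, relayed by ALPNs) onto M Kenyon cells, each sampling K channels,
under global inhibition from the APL interneuron.  In the linear rate model
KC activity is h = W · r_PN with input activity zero-mean and
unit-covariance, so the KC covariance is C = W · Wᵀ.  Each row of W has K
entries equal to 1 - α and N - K entries equal to -α, with α = A / M
(A = 100).  The representational capacity is

    dim(h) = (Tr C)² / Tr(C²),

and the K maximizing dim(h) shifts to smaller values as M grows — a
population with more KCs prefers sparser sampling.

``dimensionality`` evaluates dim(h) analytically from W (the Monte-Carlo
route via sampled inputs exists only as a test oracle).  ``observed_K``
extracts per-KC channel counts from a real or synthetic edge table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EdgeTable
from ._seed import derive_seed

__all__ = [
    "KCParams",
    "build_W",
    "dimensionality",
    "sweep_K",
    "observed_K",
    "ei_ratio",
    "KCRateModel",
    "KCDimResults",
]


@dataclass
class KCParams:
    """Rate-model parameters.

    M Kenyon cells, N input channels (58 glomeruli by default), K sampled
    channels per cell, inhibition constant A (α = A / M).
    """

    M: int
    N: int = 58
    K: int = 6
    A: float = 100.0
    n_realizations: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.K <= self.N):
            raise ValueError("K must satisfy 1 <= K <= N")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @property
    def alpha(self) -> float:
        return self.A / self.M


def build_W(M: int, N: int, K: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Random homogeneous weight matrix: per row, K entries 1 - α at
    uniformly random positions and N - K entries -α.  Rows are independent
    and every row sums to K - N·α exactly."""
    if K > N:
        raise ValueError("K must be <= N")
    W = np.full((M, N), -alpha, dtype=float)
    idx = np.argsort(rng.random((M, N)), axis=1)[:, :K]
    np.put_along_axis(W, idx, 1.0 - alpha, axis=1)
    return W


def dimensionality(W: np.ndarray) -> float:
    """dim(h) = (Tr C)² / Tr(C²) for C = W·Wᵀ (unit input covariance).

    Uses the N×N Gram matrix G = WᵀW, which shares trace and squared
    Frobenius norm with C, so the cost is O(M N²) rather than O(M² N).
    """
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        raise ValueError("W must be non-zero")
    G = W.T @ W
    tr = float(np.trace(G))
    tr2 = float((G * G).sum())
    if tr2 == 0:
        raise ValueError("Tr(C^2) is zero; dimensionality undefined")
    return tr * tr / tr2


def sweep_K(
    M: int,
    N: int,
    A: float,
    K_range,
    n_realizations: int = 20,
    seed: int = 0,
) -> "KCDimResults":
    """Mean ± sd of dim(h) over W realizations for each K.

    Common random numbers: realization r uses the same derived seed for
    every K, reducing variance in cross-K comparisons.  The argmax breaks
    ties toward smaller K.
    """
    K_range = list(K_range)
    if any(k < 1 or k > N for k in K_range):
        raise ValueError("K_range must lie within [1, N]")
    alpha = A / M
    dims = np.empty((n_realizations, len(K_range)))
    for r in range(n_realizations):
        rng = np.random.default_rng(derive_seed(seed, f"realization{r}"))
        for j, K in enumerate(K_range):
            dims[r, j] = dimensionality(build_W(M, N, K, alpha, rng))
    curve = pd.DataFrame(
        {
            "K": K_range,
            "dim_mean": dims.mean(axis=0),
            "dim_sd": dims.std(axis=0, ddof=1) if n_realizations > 1 else 0.0,
        }
    ).set_index("K")
    return KCDimResults(M=M, N=N, A=A, curve=curve, n_realizations=n_realizations)


@dataclass
class KCDimResults:
    """Per-K dimensionality curve and its maximizer."""

    M: int
    N: int
    A: float
    curve: pd.DataFrame
    n_realizations: int

    @property
    def argmax_K(self) -> int:
        means = self.curve["dim_mean"]
        return int(means.index[int(np.argmax(means.to_numpy()))])

    @property
    def max_dim(self) -> float:
        return float(self.curve["dim_mean"].max())

    def summary(self) -> str:
        return "\n".join(
            [
                "KC rate-model dimensionality sweep",
                "=" * 46,
                f"M (KCs)               {self.M:>8d}",
                f"N (channels)          {self.N:>8d}",
                f"A (inhibition)        {self.A:>8.1f}",
                f"alpha = A/M           {self.A / self.M:>8.4f}",
                f"realizations          {self.n_realizations:>8d}",
                f"K grid                {self.curve.index.min():>3d}..{self.curve.index.max():<3d}",
                f"argmax K              {self.argmax_K:>8d}",
                f"max dim(h)            {self.max_dim:>8.1f}",
            ]
        )


class KCRateModel:
    """Model-style front end: configure (M, N, A), fit a K sweep."""

    def __init__(self, M: int, N: int = 58, A: float = 100.0):
        self.M, self.N, self.A = M, N, A

    def fit(self, K_range=None, n_realizations: int = 20, seed: int = 0) -> KCDimResults:
        K_range = range(1, min(self.N, 30) + 1) if K_range is None else K_range
        return sweep_K(self.M, self.N, self.A, K_range, n_realizations, seed)


# ---------------------------------------------------------------------------
# Observed wiring statistics
# ---------------------------------------------------------------------------


def observed_K(
    edges: EdgeTable,
    channel_of: dict[str, str],
    kc_set,
    threshold: int = 1,
) -> dict:
    """Per-KC count of distinct input channels with weight >= threshold.

    ``channel_of`` maps input (ALPN) neuron ids to channel (glomerulus)
    labels and must cover every ALPN partner.  K is reported without a
    threshold by default; filtering weak connections lowers K, so a
    threshold sweep is available by calling with larger ``threshold``.
    """
    kc_set = set(kc_set)
    df = edges.df
    sub = df[df["post_id"].isin(kc_set) & df["pre_id"].isin(set(channel_of))]
    chan = sub["pre_id"].map(channel_of)
    per_chan = sub.groupby([sub["post_id"], chan])["weight"].sum()
    strong = per_chan[per_chan >= threshold]
    k = strong.groupby(level=0).size()
    k = k.reindex(sorted(kc_set), fill_value=0)
    k.index.name = "kc"
    return {"per_kc": k, "mean": float(k.mean()), "threshold": threshold}


def ei_ratio(
    edges: EdgeTable,
    excitatory: set,
    inhibitory: set,
    group_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalized excitation/inhibition ratio per KC.

    Per cell: (share of the excitatory population budget received) /
    (share of the inhibitory budget received), normalized to a population
    mean of 1.  Cells with zero inhibitory input get an infinite ratio and
    a flag.
    """
    df = edges.df
    exc = df[df["pre_id"].isin(set(excitatory))].groupby("post_id")["weight"].sum()
    inh = df[df["pre_id"].isin(set(inhibitory))].groupby("post_id")["weight"].sum()
    if exc.sum() == 0 or inh.sum() == 0:
        raise ValueError("both excitatory and inhibitory budgets must be non-zero")
    cells = sorted(set(exc.index) | set(inh.index))
    e = exc.reindex(cells, fill_value=0) / exc.sum()
    i = inh.reindex(cells, fill_value=0) / inh.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = e.to_numpy() / i.to_numpy()
    out = pd.DataFrame(
        {
            "exc_share": e,
            "inh_share": i,
            "ratio": ratio,
            "zero_inhibition": i.to_numpy() == 0,
        },
        index=pd.Index(cells, name="cell"),
    )
    finite = np.isfinite(out["ratio"])
    mean = out.loc[finite, "ratio"].mean()
    out["normalized_ratio"] = out["ratio"] / mean
    if group_of is not None:
        out["group"] = out.index.map(lambda c: group_of.get(c))
    return out
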