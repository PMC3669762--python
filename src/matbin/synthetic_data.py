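"""Seeded generators for every input the pipeline consumes.

Markov-chain genome models with controlled stationary G+C and
higher-order compositional bias produce multi-population scaffold sets
with planted bin labels; companion generators emit OTU count vectors,
mixed-type environmental tables with an optional planted gradient, and
functional-category matrices with planted site groups. Every generator
is reproducible from its seed and always returns ground truth alongside
the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from matbin.ecostats import fisher_alpha  # noqa: F401  (re-used by callers)
from matbin.funcprofile import FunctionalMatrix
from matbin.seqio import ScaffoldRecord

__all__ = [
    "GenomeModel",
    "CommunitySpec",
    "sample_genome_model",
    "generate_scaffolds",
    "generate_otu_counts",
    "generate_env_matrix",
    "generate_func_matrix",
]

_BASES = "ACGT"
_GC_MASK = np.array([0.0, 1.0, 1.0, 0.0])  # A C G T


def _stationary_gc(probs: np.ndarray, order: int) -> float:
    """Stationary G+C fraction of an order-k chain over contexts."""
    if order == 0:
        p = probs[0]
        return float(p @ _GC_MASK)
    n_ctx = 4**order
    # context transition: ctx=(x1..xk) --b--> ((ctx*4+b) mod 4^k)
    pi = np.full(n_ctx, 1.0 / n_ctx)
    idx = (np.arange(n_ctx)[:, None] * 4 + np.arange(4)[None, :]) % n_ctx
    for _ in range(500):
        new = np.zeros(n_ctx)
        np.add.at(new, idx, pi[:, None] * probs)
        if np.abs(new - pi).sum() < 1e-13:
            pi = new
            break
        pi = new
    return float(pi @ (probs @ _GC_MASK))


def _tilt(probs: np.ndarray, t: float) -> np.ndarray:
    w = np.array([1.0, t, t, 1.0])
    tilted = probs * w
    return tilted / tilted.sum(axis=1, keepdims=True)


@dataclass
class GenomeModel:
    """Order-k Markov nucleotide model with a calibrated stationary G+C."""

    label: str
    target_gc: float
    markov_order: int
    probs: np.ndarray  # (4^order, 4) conditional probabilities
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional probabilities must sum to 1 per context")

    def stationary_gc(self) -> float:
        return _stationary_gc(self.probs, self.markov_order)

    def sample_sequence(self, length: int, rng: np.random.Generator) -> str:
        """Draw one sequence of ``length`` bases from the chain."""
        if length < 1:
            raise ValueError("length must be >= 1")
        k = self.markov_order
        cum = np.cumsum(self.probs, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(length)
        out = np.empty(length, dtype=np.uint8)
        mask = 4**k - 1 if k else 0
        ctx = 0
        searchsorted = np.searchsorted
        for i in range(length):
            b = int(searchsorted(cum[ctx], u[i], side="right"))
            if b > 3:
                b = 3
            out[i] = b
            if k:
                ctx = ((ctx << 2) | b) & mask
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        return lut[out].tobytes().decode("ascii")


def sample_genome_model(
    target_gc: float,
    markov_order: int = 2,
    bias_strength: float = 0.5,
    seed: int = 0,
    label: str | None = None,
) -> GenomeModel:
    """Draw a random genome model whose stationary G+C equals ``target_gc``.

    Per-context conditional distributions are the base distribution
    (independent bases at ``target_gc``) perturbed by log-normal noise of
    scale ``bias_strength``, then exponentially tilted on G/C vs A/T so
    the stationary G+C matches the target exactly (to 1e-6).
    ``bias_strength`` 0 gives the unbiased base distribution.
    """
    if not 0 < target_gc < 1:
        raise ValueError("target_gc must be in (0, 1)")
    if markov_order < 0:
        raise ValueError("markov_order must be >= 0")
    rng = np.random.default_rng(seed)
    g = target_gc
    base = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    n_ctx = 4**markov_order
    noise = rng.normal(0.0, 1.0, size=(n_ctx, 4))
    probs = base[None, :] * np.exp(bias_strength * noise)
    probs /= probs.sum(axis=1, keepdims=True)
    if bias_strength > 0:

        def gc_err(log_t: float) -> float:
            return _stationary_gc(_tilt(probs, math.exp(log_t)), markov_order) - g

        log_t = brentq(gc_err, -20.0, 20.0, xtol=1e-12)
        probs = _tilt(probs, math.exp(log_t))
    return GenomeModel(
        label=label or f"gc{target_gc:.2f}_o{markov_order}_s{seed}",
        target_gc=target_gc,
        markov_order=markov_order,
        probs=probs,
        seed=seed,
    )


@dataclass
class CommunitySpec:
    """Recipe for a synthetic multi-population scaffold set.

    Scaffold lengths are lognormal around ``length_median_bp`` with
    log-scale ``length_sigma``, truncated (by redraw) to
    ``[min_length_bp, max_length_bp]``.
    """

    models: Sequence[tuple[GenomeModel, float]]  # (model, relative abundance)
    n_scaffolds: int
    length_median_bp: float = 15_000
    length_sigma: float = 0.5
    min_length_bp: int = 1_000
    max_length_bp: int = 130_000
    n_injection_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ab = np.array([a for _, a in self.models], dtype=float)
        if len(ab) == 0 or np.any(ab < 0) or not math.isclose(ab.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("model abundances must be nonnegative and sum to 1")
        if not 0 <= self.n_injection_rate < 1:
            raise ValueError("n_injection_rate must be in [0, 1)")


def _draw_length(spec: CommunitySpec, rng: np.random.Generator) -> int:
    mu = math.log(spec.length_median_bp)
    for _ in range(1000):
        L = int(round(rng.lognormal(mu, spec.length_sigma)))
        if spec.min_length_bp <= L <= spec.max_length_bp:
            return L
    raise RuntimeError("length truncation bounds reject nearly all draws")


def generate_scaffolds(
    spec: CommunitySpec,
) -> tuple[list[ScaffoldRecord], dict[str, str]]:
    """Generate a scaffold set plus its truth table (id -> model label).

    Each scaffold's source model is chosen by relative abundance; with a
    positive ``n_injection_rate`` that fraction of bases is replaced by
    'N'. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [m.label for m, _ in spec.models]
    ab = np.array([a for _, a in spec.models])
    choices = rng.choice(len(labels), size=spec.n_scaffolds, p=ab)
    records: list[ScaffoldRecord] = []
    truth: dict[str, str] = {}
    for i, mi in enumerate(choices):
        model = spec.models[mi][0]
        L = _draw_length(spec, rng)
        seq = model.sample_sequence(L, rng)
        if spec.n_injection_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hit = rng.random(L) < spec.n_injection_rate
            arr[hit] = ord("N")
            seq = arr.tobytes().decode("ascii")
        sid = f"scaffold_{i:05d}"
        records.append(ScaffoldRecord(id=sid, sequence=seq))
        truth[sid] = labels[mi]
    return records, truth


def generate_otu_counts(
    S_true: int,
    N: int,
    abundance_model: str = "logseries",
    seed: int = 0,
    lognormal_sigma: float = 1.0,
) -> dict[str, int]:
    """Sample an OTU count vector of N individuals.

    ``logseries``: species abundances are drawn from Fisher's log-series
    with the alpha implied by (S_true, N) — species are accumulated
    until N individuals are reached, so the realized richness is close
    to (not exactly) S_true and ``fisher_alpha`` is consistent for the
    implied alpha. ``lognormal``: exactly S_true species with lognormal
    relative abundances, N individuals multinomial.
    """
    if S_true < 1 or N < 1:
        raise ValueError("S_true and N must be >= 1")
    rng = np.random.default_rng(seed)
    if abundance_model == "logseries":
        if S_true >= N:
            raise ValueError("logseries model needs S_true < N")
        alpha = brentq(
            lambda a: a * math.log1p(N / a) - S_true, 1e-9, 1e12, xtol=1e-10
        )
        x = N / (N + alpha)
        counts: list[int] = []
        total = 0
        while total < N:
            c = int(rng.logseries(x))
            if total + c > N:
                c = N - total
            counts.append(c)
            total += c
        arr = np.array([c for c in counts if c > 0])
    elif abundance_model == "lognormal":
        props = rng.lognormal(0.0, lognormal_sigma, size=S_true)
        props /= props.sum()
        arr = rng.multinomial(N, props)
        arr = arr[arr > 0]
    else:
        raise ValueError(f"unknown abundance model {abundance_model!r}")
    return {f"otu_{i:04d}": int(c) for i, c in enumerate(arr)}


def generate_env_matrix(
    n_sites: int,
    n_numeric: int = 4,
    n_factor: int = 1,
    effect_axis: float = 0.0,
    seed: int = 0,
    n_levels: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Mixed-type site table with an optional planted gradient.

    Sites carry a latent ordering; non-planted numeric variables load
    unit-strength on it (with noise SD 0.7) so the Gower/PCoA ordination
    tracks the gradient, and variable ``num_0`` loads with strength
    ``effect_axis`` and noise SD 1 (0 means fully independent — the null
    case). Factor columns are independent categorical draws. Returns
    (table, truth) where truth records the latent gradient and the
    planted variable name.
    """
    if n_sites < 2 or n_numeric < 1:
        raise ValueError("need >= 2 sites and >= 1 numeric variable")
    rng = np.random.default_rng(seed)
    gradient = np.linspace(-1.0, 1.0, n_sites)
    cols: dict[str, object] = {}
    cols["num_0"] = effect_axis * gradient + rng.normal(0, 1.0, n_sites)
    for v in range(1, n_numeric):
        cols[f"num_{v}"] = gradient + rng.normal(0, 0.7, n_sites)
    for f in range(n_factor):
        levels = [f"L{j}" for j in range(n_levels)]
        cols[f"fac_{f}"] = pd.Series(
            rng.choice(levels, size=n_sites), dtype=object
        ).to_numpy()
    df = pd.DataFrame(cols, index=[f"site_{i:02d}" for i in range(n_sites)])
    truth = {"gradient": gradient, "planted_variable": "num_0", "effect": effect_axis}
    return df, truth


def generate_func_matrix(
    n_sites: int,
    n_categories: int = 40,
    n_groups: int = 3,
    effect_size: float = 1.5,
    seed: int = 0,
    noise_sd: float = 0.2,
) -> tuple[FunctionalMatrix, dict[str, int]]:
    """Category x site count matrix with planted site groups.

    Site i belongs to group i mod n_groups; each (category, group) pair
    has a log-abundance shift of scale ``effect_size``. Returns (raw
    count matrix, truth: site -> group index).
    """
    if n_groups > n_sites:
        raise ValueError("more groups than sites")
    rng = np.random.default_rng(seed)
    groups = np.arange(n_sites) % n_groups
    base = rng.normal(4.0, 0.5, size=n_categories)  # log mean abundance
    shift = rng.normal(0.0, 1.0, size=(n_categories, n_groups))
    log_mu = (
        base[:, None]
        + effect_size * shift[:, groups]
        + rng.normal(0.0, noise_sd, size=(n_categories, n_sites))
    )
    counts = rng.poisson(np.exp(log_mu)).astype(float)
    sites = [f"site_{i:02d}" for i in range(n_sites)]
    cats = [f"cat_{c:03d}" for c in range(n_categories)]
    fm = FunctionalMatrix(
        data=pd.DataFrame(counts, index=cats, columns=sites), normalization="raw"
    )
    truth = {s: int(g) for s, g in zip(sites, groups)}
    return fm, truth
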