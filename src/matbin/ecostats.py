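"""Environmental and diversity statistics.

Gower dissimilarity of mixed numeric/categorical site tables, vector
fitting of environmental variables onto ordination scores with
permutation tests, and the classic alpha-diversity estimators (Chao1,
ACE, Shannon, reciprocal Simpson, Fisher's alpha) with analytic
rarefaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "EnvFitResult",
    "DiversityReport",
    "read_env_table",
    "gower_distance",
    "fit_env_variables",
    "chao1",
    "ace",
    "shannon",
    "simpson_reciprocal",
    "fisher_alpha",
    "rarefaction",
    "diversity_report",
]


# ---------------------------------------------------------------------------
# environment tables and Gower dissimilarity


def parse_env_value(raw: str) -> tuple[float, str | None]:
    """Parse one numeric cell; ``"<x"`` (below detection) becomes x/2.

    Returns (value, provenance note or None).
    """
    raw = raw.strip()
    if raw.startswith("<"):
        x = float(raw[1:])
        return x / 2.0, f"below-detection '<{raw[1:]}' -> {x / 2.0}"
    return float(raw), None


def read_env_table(
    path: str | Path, schema: Mapping[str, str] | str | Path | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Read a tab-delimited site x variable table with mixed types.

    ``schema`` maps column name to ``"numeric"`` or ``"factor"`` (a
    two-column TSV path is accepted). Without a schema, columns that
    parse fully as numbers (allowing ``<x`` below-detection entries and
    blanks) are numeric, the rest factors. The first column is the site
    id. Returns (dataframe indexed by site, provenance notes).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.set_index(df.columns[0])
    if isinstance(schema, (str, Path)):
        sdf = pd.read_csv(schema, sep="\t", comment="#", dtype=str, header=None)
        schema = dict(zip(sdf.iloc[:, 0], sdf.iloc[:, 1]))
    notes: list[str] = []
    out = {}
    for col in df.columns:
        kind = schema.get(col) if schema else None
        raw = df[col]
        if kind == "factor":
            out[col] = raw.astype(object)
            continue
        parsed = []
        ok = True
        for site, cell in raw.items():
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                parsed.append(np.nan)
                continue
            try:
                val, note = parse_env_value(str(cell))
            except ValueError:
                ok = False
                break
            if note:
                notes.append(f"{col}[{site}]: {note}")
            parsed.append(val)
        if ok:
            out[col] = pd.Series(parsed, index=df.index, dtype=float)
        elif kind == "numeric":
            raise ValueError(f"{path}: column {col!r} declared numeric but not parseable")
        else:
            out[col] = raw.astype(object)
    return pd.DataFrame(out, index=df.index), notes


def _is_numeric(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col)


def gower_distance(env: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity of a mixed-type site table.

    d(i,j) = sum_v w_v * delta_v / sum_v w_v with delta = range-scaled
    absolute difference (numeric) or mismatch indicator (categorical);
    a variable gets weight 0 for a pair when either value is missing or
    (numeric) its range is 0. A pair with no comparable variable raises.
    """
    if env.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    n = env.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in env.columns:
        s = env[col]
        if s.notna().sum() < 1:
            raise ValueError(f"variable {col!r} has no non-missing value")
        if _is_numeric(s):
            x = s.to_numpy(dtype=float)
            present = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if present.any() else 0.0
            if rng == 0:
                continue  # zero range -> weight 0 for all pairs
            w = np.outer(present, present).astype(float)
            with np.errstate(invalid="ignore"):
                delta = np.abs(x[:, None] - x[None, :]) / rng
            delta = np.where(w > 0, delta, 0.0)
        else:
            vals = s.to_numpy(dtype=object)
            present = np.array([not (v is None or (isinstance(v, float) and math.isnan(v))) for v in vals])
            w = np.outer(present, present).astype(float)
            delta = (vals[:, None] != vals[None, :]).astype(float)
            delta = np.where(w > 0, delta, 0.0)
        num += w * delta
        den += w
    if np.any((den == 0) & ~np.eye(n, dtype=bool)):
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"sites {env.index[i]!r} and {env.index[j]!r} share no comparable variable"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry
    return pd.DataFrame(d, index=env.index, columns=env.index)


# ---------------------------------------------------------------------------
# envfit-style variable fitting


@dataclass
class EnvFitResult:
    """Per-variable fit of environmental variables onto ordination scores."""

    variables: dict[str, dict] = field(default_factory=dict)
    n_permutations: int = 0

    def r_squared(self, var: str) -> float:
        return self.variables[var]["r_squared"]

    def p_value(self, var: str) -> float:
        return self.variables[var]["p_value"]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            v: {"kind": d["kind"], "r_squared": d["r_squared"], "p_value": d["p_value"]}
            for v, d in self.variables.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")


def _numeric_fit(scores: np.ndarray, y: np.ndarray, n_perm: int, rng) -> dict:
    """r^2 of the least-squares projection of y onto score space, with
    permutation p-value (variable shuffled across sites)."""
    yc = y - y.mean()
    sst = float(yc @ yc)
    Q, _ = np.linalg.qr(scores - scores.mean(axis=0))
    if sst == 0:
        return {
            "r_squared": 0.0,
            "p_value": 1.0,
            "direction": np.zeros(scores.shape[1]),
            "note": "constant variable",
        }
    proj = Q.T @ yc
    r2 = float(proj @ proj) / sst
    coef = np.linalg.lstsq(scores - scores.mean(axis=0), yc, rcond=None)[0]
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else coef
    # all permutations at once: rows of P are shuffled centered y
    P = np.empty((n_perm, y.size))
    for t in range(n_perm):
        P[t] = yc[rng.permutation(y.size)]
    perm_proj = P @ Q  # (n_perm, axes)
    perm_r2 = np.einsum("ij,ij->i", perm_proj, perm_proj) / np.einsum(
        "ij,ij->i", P, P
    )
    p = (1 + int(np.sum(perm_r2 >= r2 - 1e-12))) / (1 + n_perm)
    return {"r_squared": r2, "p_value": p, "direction": direction, "note": None}


def _factor_r2(scores_c: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    sst = float(np.sum(scores_c**2))
    if sst == 0:
        return 0.0
    ssw = 0.0
    for g in range(n_levels):
        grp = scores_c[codes == g]
        if len(grp):
            ssw += float(np.sum((grp - grp.mean(axis=0)) ** 2))
    return 1.0 - ssw / sst


def _factor_fit(scores: np.ndarray, labels: np.ndarray, n_perm: int, rng) -> dict:
    codes, levels = pd.factorize(labels)
    scores_c = scores - scores.mean(axis=0)
    r2 = _factor_r2(scores_c, codes, len(levels))
    centroids = {
        str(lev): scores[codes == g].mean(axis=0) for g, lev in enumerate(levels)
    }
    ge = 0
    for _ in range(n_perm):
        perm = codes[rng.permutation(codes.size)]
        if _factor_r2(scores_c, perm, len(levels)) >= r2 - 1e-12:
            ge += 1
    note = "single level" if len(levels) < 2 else None
    return {
        "r_squared": r2 if len(levels) > 1 else 0.0,
        "p_value": (1 + ge) / (1 + n_perm),
        "centroids": centroids,
        "note": note,
    }


def fit_env_variables(
    scores,
    env: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> EnvFitResult:
    """Fit each environmental variable onto ordination scores.

    Numeric variables score the r^2 of their least-squares projection
    onto the score space (fitted direction reported); factors score the
    among/total sum of squares of level centroids. Significance is the
    add-one permutation estimator with the variable shuffled across
    sites. Sites with a missing value are dropped for that variable.
    """
    if hasattr(scores, "scores"):  # OrdinationResult
        S = np.asarray(scores.scores, dtype=float)
    else:
        S = np.asarray(scores, dtype=float)
    if S.ndim != 2:
        raise ValueError("scores must be 2-D (sites x axes)")
    n, axes = S.shape
    if env.shape[0] != n:
        raise ValueError(f"env has {env.shape[0]} sites but scores have {n}")
    if n < axes + 1:
        raise ValueError(f"need more sites ({n}) than axes + 1 ({axes + 1})")
    rng = np.random.default_rng(seed)
    result = EnvFitResult(n_permutations=n_permutations)
    for col in env.columns:
        s = env[col]
        if _is_numeric(s):
            mask = s.notna().to_numpy()
            fit = _numeric_fit(S[mask], s.to_numpy(dtype=float)[mask], n_permutations, rng)
            fit["kind"] = "numeric"
        else:
            mask = s.notna().to_numpy()
            fit = _factor_fit(S[mask], s.to_numpy(dtype=object)[mask], n_permutations, rng)
            fit["kind"] = "factor"
        if fit["note"]:
            warnings.warn(f"variable {col!r}: {fit['note']}", stacklevel=2)
        result.variables[col] = fit
    return result


# ---------------------------------------------------------------------------
# alpha diversity


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()))
    else:
        arr = np.asarray(counts)
    if arr.size and not np.all(arr == np.floor(arr)):
        raise ValueError("counts must be integers")
    arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("need at least one individual")
    return arr


def chao1(counts) -> float:
    """Chao1 richness: S_obs + f1^2/(2 f2); bias-corrected
    S_obs + f1(f1-1)/(2(f2+1)) when f2 = 0."""
    n = _as_counts(counts)
    s_obs = n.size
    f1 = int(np.sum(n == 1))
    f2 = int(np.sum(n == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator (classic form).

    Species with count <= ``rare_threshold`` are "rare". Falls back to
    Chao1 (with a warning) when the coverage estimate is 0, i.e. all
    rare species are singletons.
    """
    n = _as_counts(counts)
    rare = n[n <= rare_threshold]
    s_abund = int(np.sum(n > rare_threshold))
    s_rare = rare.size
    if s_rare == 0:
        return float(n.size)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0:
        warnings.warn("ACE coverage is 0 (all rare species are singletons); "
                      "falling back to Chao1", stacklevel=2)
        return chao1(counts)
    fsum = 0.0
    for i in range(1, rare_threshold + 1):
        fi = int(np.sum(rare == i))
        fsum += i * (i - 1) * fi
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max(s_rare / c_ace * fsum / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy H = -sum p_i log p_i (natural log by default)."""
    n = _as_counts(counts)
    p = n / n.sum()
    return float(-np.sum(p * np.log(p)) / math.log(base))


def simpson_reciprocal(counts) -> float:
    """Reciprocal Simpson index 1 / sum p_i^2 (proportion form)."""
    n = _as_counts(counts)
    p = n / n.sum()
    return float(1.0 / np.sum(p**2))


def fisher_alpha(counts, tol: float = 1e-12) -> float:
    """Fisher's alpha: the root of S = alpha * ln(1 + N/alpha).

    Solved by bracketed root-finding; the residual at the returned alpha
    is below 1e-9. Requires S < N (otherwise no finite solution).
    """
    n = _as_counts(counts)
    s, N = n.size, int(n.sum())
    if s >= N:
        raise ValueError(
            f"Fisher's alpha undefined for S ({s}) >= N ({N}): "
            "alpha * ln(1 + N/alpha) < N for all finite alpha"
        )

    def f(a: float) -> float:
        return a * math.log1p(N / a) - s

    lo = 1e-12
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e15:  # pragma: no cover
            raise RuntimeError("failed to bracket Fisher's alpha")
    alpha = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)
    assert abs(f(alpha)) < 1e-9
    return float(alpha)


def rarefaction(counts, depths: Sequence[int]) -> list[tuple[int, float]]:
    """Analytic rarefaction: E[S_m] = sum_i [1 - C(N-n_i, m)/C(N, m)].

    Depths must satisfy 0 <= m <= N. Computed with log-gamma for
    numerical stability at large N.
    """
    n = _as_counts(counts)
    N = int(n.sum())
    curve: list[tuple[int, float]] = []
    for m in depths:
        m = int(m)
        if m > N:
            raise ValueError(f"rarefaction depth {m} exceeds total count {N}")
        if m < 0:
            raise ValueError("rarefaction depth must be >= 0")
        # log C(N-n_i, m) - log C(N, m); absent species (N-n_i < m) retain prob 0
        keep = (N - n) >= m
        log_denom = gammaln(N + 1) - gammaln(m + 1) - gammaln(N - m + 1)
        log_num = (
            gammaln(N - n[keep] + 1)
            - gammaln(m + 1)
            - gammaln(N - n[keep] - m + 1)
        )
        prob_absent = np.exp(log_num - log_denom)
        expected = float(np.sum(keep) - prob_absent.sum() + np.sum(~keep))
        curve.append((m, expected))
    return curve


@dataclass
class DiversityReport:
    """All alpha-diversity summaries for one count vector."""

    s_obs: int
    chao1: float
    ace: float
    shannon: float
    simpson_reciprocal: float
    fisher_alpha: float | None
    rarefaction_curve: list[tuple[int, float]]


def diversity_report(counts, rarefaction_points: int = 20) -> DiversityReport:
    """Compute every supported index plus an evenly spaced rarefaction curve.

    ``fisher_alpha`` is ``None`` when undefined (every individual its own
    species).
    """
    n = _as_counts(counts)
    N = int(n.sum())
    depths = sorted(set(np.linspace(1, N, min(rarefaction_points, N), dtype=int)))
    try:
        fa = fisher_alpha(n)
    except ValueError:
        fa = None
    return DiversityReport(
        s_obs=n.size,
        chao1=chao1(n),
        ace=ace(n),
        shannon=shannon(n),
        simpson_reciprocal=simpson_reciprocal(n),
        fisher_alpha=fa,
        rarefaction_curve=rarefaction(n, depths),
    )
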