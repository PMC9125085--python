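"""Community statistics: alpha diversity, Bray–Curtis, PCoA, PERMANOVA,
dispersion homogeneity, sequential ANOVA, Tukey HSD, qPCR normalisation.

All permutation procedures are implemented directly on the distance matrix
(no external ecology package) and are bit-reproducible given a seed.
Sums of squares are sequential (Type I): each term is assessed after the
terms preceding it in the user's column order, matching the order-dependent
semantics of the classical multi-factor partitioning.

Permutation p-values use the (1 + #{permuted ≥ observed}) / (1 + N)
estimator, so a reported p can never be 0 and is bounded below by 1/(N+1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .model import AsvCountTable, ConfigurationError, ValidationError
from .preprocess import relative_abundance

_RANK_TOL = 1e-9


# -- containers -----------------------------------------------------------


class DistanceMatrix:
    """Symmetric sample × sample dissimilarity matrix with zero diagonal."""

    def __init__(self, sample_ids: Sequence[str], data) -> None:
        self.sample_ids = list(sample_ids)
        data = np.asarray(data, dtype=float)
        n = len(self.sample_ids)
        if data.shape != (n, n):
            raise ValidationError(f"distance matrix shape {data.shape} != ({n},{n})")
        if not np.allclose(data, data.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(data), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal is not zero")
        if (data < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.data = (data + data.T) / 2.0
        np.fill_diagonal(self.data, 0.0)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return DistanceMatrix(keep, self.data[np.ix_(idx, idx)])


@dataclass
class PermutationTestResult:
    """Outcome of one permutation test term (PERMANOVA or dispersion)."""

    term: str
    statistic: float
    df: int
    r_squared: float | None
    n_permutations: int
    p_value: float


@dataclass
class QpcrQuantity:
    """One sample's qPCR measurement and its normalisation context.

    ``denom`` is grams of soil extracted or millilitres of snow/flow-through
    filtered; eluate/template volumes convert a per-reaction copy number to
    a per-extraction one.
    """

    sample_id: str
    copies_per_reaction: float
    eluate_volume_ul: float
    template_volume_ul: float
    denom: float | None

    @property
    def copies_per_unit(self) -> float:
        return qpcr_normalize(self)


# -- alpha diversity ------------------------------------------------------


def richness(sample_counts) -> int:
    """Number of taxa with at least one read."""
    counts = np.asarray(sample_counts)
    if counts.sum() <= 0:
        raise ValidationError("sample has zero total count")
    return int((counts > 0).sum())


def shannon(sample_counts) -> float:
    """Shannon diversity H = −Σ p ln p in nats over detected taxa."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("sample has zero total count")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


# -- beta diversity -------------------------------------------------------


def bray_curtis(data, sample_ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Bray–Curtis dissimilarity d(x,y) = Σ|x−y| / Σ(x+y) between samples.

    ``data`` is an :class:`AsvCountTable` (normalised to relative abundance
    first, as the dissimilarity is conventionally computed on compositions)
    or a taxa × samples array of abundances used as-is.

    Bray–Curtis is a semimetric: it is bounded in [0,1] but need not obey
    the triangle inequality.
    """
    if isinstance(data, AsvCountTable):
        sample_ids = data.sample_ids
        matrix = relative_abundance(data)
    else:
        matrix = np.asarray(data, dtype=float)
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(matrix.shape[1])]
    n = matrix.shape[1]
    if n < 2:
        raise ValidationError("Bray–Curtis needs >= 2 samples")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = matrix[:, i], matrix[:, j]
            denom = float((x + y).sum())
            if denom == 0:
                raise ValidationError(
                    f"samples {sample_ids[i]!r} and {sample_ids[j]!r} are both empty"
                )
            out[i, j] = out[j, i] = float(np.abs(x - y).sum()) / denom
    return DistanceMatrix(sample_ids, out)


# -- ordination -----------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = −½ J D² J."""
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples × positive axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives included)
    sample_ids: list[str]


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical (metric) multidimensional scaling.

    Eigendecomposes the Gower-centred matrix; axes are ordered by decreasing
    eigenvalue.  Negative eigenvalues (possible for semimetric inputs such
    as Bray–Curtis) are reported but their axes are not included in the
    coordinates; no Cailliez/Lingoes correction is applied.
    """
    g = _gower_center(dm.data)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = np.max(np.abs(eigvals)) if len(eigvals) else 0.0
    tol = max(scale, 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(int(pos.sum()))],
    )
    return PcoaResult(frame, eigvals, list(dm.sample_ids))


# -- PERMANOVA ------------------------------------------------------------


def _orthonormal_increment(basis: np.ndarray, new_cols: np.ndarray) -> np.ndarray:
    """Orthonormal columns spanning what ``new_cols`` adds beyond ``basis``."""
    resid = new_cols - basis @ (basis.T @ new_cols)
    if resid.size == 0:
        return np.zeros((basis.shape[0], 0))
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    keep = s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)
    return u[:, keep]


def _one_hot(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _factor_frame(factors, n: int) -> pd.DataFrame:
    if isinstance(factors, pd.DataFrame):
        frame = factors
    elif isinstance(factors, Mapping):
        frame = pd.DataFrame(factors)
    else:
        frame = pd.DataFrame({"factor": list(factors)})
    if len(frame) != n:
        raise ValidationError(f"{len(frame)} factor rows for {n} samples")
    return frame


def permanova(
    dm: DistanceMatrix,
    factors,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> list[PermutationTestResult]:
    """Permutational multivariate ANOVA on a distance matrix.

    Sums of squares are partitioned sequentially over the ordered factors
    (the first factor is assessed alone, each later factor after those
    before it).  The pseudo-F for each term uses the residual from the full
    model; significance comes from shuffling sample labels with a seeded
    generator.  ``n_permutations="exact"`` enumerates every permutation
    (feasible only for small n) and reports the exact enumeration p-value
    #{F_perm ≥ F_obs} / n! (the identity permutation included).
    """
    n = len(dm)
    frame = _factor_frame(factors, n)
    g = _gower_center(dm.data)
    ss_total = float(np.trace(g))

    # cumulative orthonormal bases: intercept, then each factor in order
    bases: list[np.ndarray] = []
    dfs: list[int] = []
    basis = np.ones((n, 1)) / np.sqrt(n)
    for col in frame.columns:
        levels = frame[col].nunique()
        if levels < 2:
            raise ValidationError(f"factor {col!r} has fewer than 2 levels")
        inc = _orthonormal_increment(basis, _one_hot(frame[col].to_numpy()))
        if inc.shape[1] == 0:
            raise ValidationError(
                f"factor {col!r} is confounded with preceding factors"
            )
        basis = np.hstack([basis, inc])
        bases.append(basis.copy())
        dfs.append(inc.shape[1])
    rank_full = basis.shape[1]
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")

    # hat matrices of the cumulative models (intercept excluded: G is centred)
    hats = np.stack([b[:, 1:] @ b[:, 1:].T for b in bases])
    df_arr = np.array(dfs, dtype=float)

    def batch_f(gmats: np.ndarray) -> np.ndarray:
        """Pseudo-F per term for a (batch, n, n) stack of G matrices."""
        cum = np.einsum("kij,pij->pk", hats, gmats)
        ss_terms = np.diff(cum, axis=1, prepend=0.0)
        ss_res = np.trace(gmats, axis1=1, axis2=2) - cum[:, -1]
        return (ss_terms / df_arr) / (ss_res / df_resid)[:, None]

    f_obs = batch_f(g[None])[0]
    cum_obs = np.einsum("kij,ij->k", hats, g)
    ss_terms = np.diff(cum_obs, prepend=0.0)
    r2 = ss_terms / ss_total if ss_total > 0 else np.zeros_like(ss_terms)

    chunk = max(1, int(2**22 // (n * n)))  # keep permuted stacks ~32 MB
    count = np.zeros(len(bases))
    if n_permutations == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        for start in range(0, len(perms), chunk):
            idx = perms[start : start + chunk]
            gp = g[idx[:, :, None], idx[:, None, :]]
            count += (batch_f(gp) >= f_obs - 1e-12).sum(axis=0)
        p_values = count / len(perms)
        n_perm_reported = len(perms)
    else:
        rng = np.random.default_rng(seed)
        remaining = int(n_permutations)
        base_idx = np.arange(n)
        while remaining > 0:
            m = min(chunk, remaining)
            idx = rng.permuted(np.tile(base_idx, (m, 1)), axis=1)
            gp = g[idx[:, :, None], idx[:, None, :]]
            count += (batch_f(gp) >= f_obs - 1e-12).sum(axis=0)
            remaining -= m
        p_values = (1.0 + count) / (1.0 + int(n_permutations))
        n_perm_reported = int(n_permutations)

    return [
        PermutationTestResult(
            term=str(col),
            statistic=float(f_obs[i]),
            df=int(dfs[i]),
            r_squared=float(r2[i]),
            n_permutations=n_perm_reported,
            p_value=float(p_values[i]),
        )
        for i, col in enumerate(frame.columns)
    ]


# -- dispersion homogeneity (betadisper) ----------------------------------


def _embedding(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary PCoA coordinates (for negative eigenvalues)."""
    g = _gower_center(dm.data)
    eigvals, eigvecs = np.linalg.eigh(g)
    scale = max(1.0, float(np.max(np.abs(eigvals))) if len(eigvals) else 1.0)
    tol = scale * 1e-10
    pos = eigvals > tol
    neg = eigvals < -tol
    x = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    y = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return x, y


def _centroid_distances(
    x: np.ndarray, y: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    z2 = np.empty(len(labels))
    for lvl in pd.unique(labels):
        mask = labels == lvl
        cx = x[mask].mean(axis=0) if x.size else np.zeros(0)
        cy = y[mask].mean(axis=0) if y.size else np.zeros(0)
        d2 = ((x[mask] - cx) ** 2).sum(axis=1) if x.size else 0.0
        d2_neg = ((y[mask] - cy) ** 2).sum(axis=1) if y.size else 0.0
        z2[mask] = d2 - d2_neg  # imaginary axes subtract
    return np.sqrt(np.clip(z2, 0.0, None))


def _oneway_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ssb = ssw = 0.0
    k = 0
    for lvl in pd.unique(labels):
        grp = values[labels == lvl]
        ssb += len(grp) * (grp.mean() - grand) ** 2
        ssw += ((grp - grp.mean()) ** 2).sum()
        k += 1
    dfb, dfw = k - 1, len(values) - k
    # sums of squares at rounding-noise scale are treated as exactly zero
    tol = (1e-8 * max(1.0, float(np.max(np.abs(values))))) ** 2 * len(values)
    if ssw <= tol:
        return 0.0 if ssb <= tol else float("inf")
    if ssb <= tol:
        return 0.0
    return (ssb / dfb) / (ssw / dfw)


def dispersion_homogeneity(
    dm: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Test homogeneity of multivariate dispersion across groups.

    Each sample's distance to its group centroid is measured in the full
    PCoA embedding (negative-eigenvalue axes contribute negatively to the
    squared distance); the F statistic is the one-way ANOVA F on those
    distances.  The permutation test reshuffles group labels and refits
    centroids and distances for each permutation.
    """
    labels = np.asarray(list(groups))
    if len(labels) != len(dm):
        raise ValidationError("group labels do not match distance matrix")
    levels, sizes = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("dispersion test needs >= 2 groups")
    if (sizes < 2).any():
        small = levels[sizes < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    x, y = _embedding(dm)
    z = _centroid_distances(x, y, labels)
    if np.max(z) <= 1e-12:
        # all samples coincide: no dispersion anywhere, nothing to test
        return PermutationTestResult(
            term="dispersion", statistic=0.0, df=len(levels) - 1,
            r_squared=None, n_permutations=0, p_value=1.0,
        )
    f_obs = _oneway_f(z, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_permutations)):
        perm_labels = labels[rng.permutation(len(labels))]
        z_perm = _centroid_distances(x, y, perm_labels)
        if _oneway_f(z_perm, perm_labels) >= f_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + int(n_permutations))
    return PermutationTestResult(
        term="dispersion", statistic=float(f_obs), df=int(len(levels) - 1),
        r_squared=None, n_permutations=int(n_permutations), p_value=float(p),
    )


# -- factorial ANOVA ------------------------------------------------------


def anova_factorial(
    response: Sequence[float],
    factors,
    terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sequential (Type I) ANOVA with main effects and interactions.

    ``terms`` are factor column names or colon-joined interactions
    (``"rate:treat"``), fitted in order via nested least-squares
    projections.  Returns a tidy table (term, df, sum_sq, F, p) with the
    residual row last.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    frame = _factor_frame(factors, n)
    if terms is None:
        terms = list(frame.columns)
    basis = np.ones((n, 1)) / np.sqrt(n)
    rows = []
    y_centered_ss = float(((y - y.mean()) ** 2).sum())
    explained = 0.0
    term_info = []
    for term in terms:
        cols = term.split(":")
        for c in cols:
            if c not in frame.columns:
                raise ValidationError(f"unknown factor {c!r} in term {term!r}")
        combo = frame[cols].astype(str).agg("␟".join, axis=1).to_numpy()
        inc = _orthonormal_increment(basis, _one_hot(combo))
        if inc.shape[1] == 0:
            raise ValidationError(f"term {term!r} is aliased with earlier terms")
        ss = float(((inc.T @ y) ** 2).sum())
        basis = np.hstack([basis, inc])
        explained += ss
        term_info.append((term, inc.shape[1], ss))
    sse = max(y_centered_ss - explained, 0.0)
    dfe = n - basis.shape[1]
    if dfe < 1:
        raise ValidationError("no residual degrees of freedom")
    mse = sse / dfe
    for term, df, ss in term_info:
        if ss <= 1e-12 * max(1.0, y_centered_ss):
            fval, p = 0.0, 1.0
        elif mse <= 1e-300:
            fval, p = float("inf"), 0.0
        else:
            fval = (ss / df) / mse
            p = float(f_dist.sf(fval, df, dfe))
        rows.append({"term": term, "df": df, "sum_sq": ss, "F": fval, "p": p})
    rows.append(
        {"term": "Residual", "df": dfe, "sum_sq": sse, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA over a dict of group → values: (F, df1, df2, p)."""
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    values = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    table = anova_factorial(values, pd.DataFrame({"group": labels}))
    row = table.iloc[0]
    resid = table.iloc[-1]
    p = 1.0 if np.isnan(row["p"]) else float(row["p"])
    return float(row["F"]), int(row["df"]), int(resid["df"]), p


# -- Tukey HSD ------------------------------------------------------------


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    family_correction: str = "none",
    n_families: int = 1,
) -> pd.DataFrame:
    """Pairwise Tukey–Kramer comparisons with optional Bonferroni scaling.

    The studentized-range p-value for each pair uses the pooled within-group
    variance.  ``family_correction="bonferroni"`` multiplies every p by
    ``n_families`` (capped at 1) — for when several whole HSD families are
    tested side by side.
    """
    if family_correction not in ("none", "bonferroni"):
        raise ValueError("family_correction must be 'none' or 'bonferroni'")
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("Tukey HSD needs >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    sizes = {k: len(v) for k, v in arrays.items()}
    if min(sizes.values()) < 1:
        raise ValidationError("empty group")
    k = len(names)
    n_total = sum(sizes.values())
    dfw = n_total - k
    if dfw < 1:
        raise ValidationError("no within-group degrees of freedom")
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    msw = ssw / dfw
    mult = n_families if family_correction == "bonferroni" else 1
    rows = []
    for a, b in itertools.combinations(names, 2):
        diff = arrays[a].mean() - arrays[b].mean()
        if msw <= 1e-300:
            p = 1.0 if abs(diff) <= 1e-12 else 0.0  # limit of a vanishing MSW
            q = 0.0 if abs(diff) <= 1e-12 else float("inf")
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, dfw))
        rows.append(
            {
                "group1": a,
                "group2": b,
                "diff": float(diff),
                "q": float(q),
                "p_adj": min(1.0, p * mult),
            }
        )
    return pd.DataFrame(rows)


# -- qPCR -----------------------------------------------------------------


def qpcr_normalize(q: QpcrQuantity) -> float:
    """Copies per g soil or per ml filtered:
    copies/reaction × (eluate volume / template volume) / denom."""
    if q.denom is None:
        raise ConfigurationError(
            f"sample {q.sample_id!r}: missing normalisation denominator"
        )
    if q.denom <= 0 or q.template_volume_ul <= 0:
        raise ValidationError(
            f"sample {q.sample_id!r}: denom and template volume must be positive"
        )
    if q.copies_per_reaction < 0:
        raise ValidationError(f"sample {q.sample_id!r}: negative copy number")
    return (
        q.copies_per_reaction
        * (q.eluate_volume_ul / q.template_volume_ul)
        / q.denom
    )
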