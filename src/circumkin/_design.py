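"""Fixed-effects design matrices with sum-to-zero factor coding.

Type-III Wald tests are only meaningful under sum-to-zero contrasts, so all
model matrices in this package are built here with that coding: a factor
with levels ``l0 < l1 < ... < lm`` contributes columns ``l0 .. l(m-1)``
taking value 1 at their own level, -1 at the last level and 0 elsewhere.
Interaction columns are elementwise products of the component columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Design", "build_design"]


class RankDeficientError(ValueError):
    """Fixed-effects matrix is rank deficient (aliased terms)."""


def _is_factor(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s)


@dataclass
class Design:
    """A realized fixed-effects design.

    Attributes
    ----------
    matrix : ndarray (n, p)
        Design matrix, intercept first.
    names : list of str
        Column names (``Intercept``, ``factor[level]``, products with ``:``).
    term_slices : dict
        Term -> column indices.
    factor_levels : dict
        Factor -> ordered levels, for building prediction/EMM grids.
    terms : list of str
        The term list the design was built from.
    """

    matrix: np.ndarray
    names: list[str]
    term_slices: dict[str, np.ndarray]
    factor_levels: dict[str, list]
    numeric_means: dict[str, float]
    terms: list[str]

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        """Encode new rows with the same coding (levels must be known)."""
        return _encode(df, self.terms, self.factor_levels, self.numeric_means)[0]

    def emm_rows(self, factors: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
        """Estimated-marginal-mean rows for the cells of ``factors``.

        Builds the full factorial grid over every factor in the model,
        encodes it, and averages the encoded rows within each cell of the
        requested factors (equal weighting over the remaining factors);
        numeric covariates are held at their training means.
        """
        unknown = [f for f in factors if f not in self.factor_levels]
        if unknown:
            raise ValueError(f"not model factors: {unknown}")
        grids = [self.factor_levels[f] for f in self.factor_levels]
        mesh = pd.MultiIndex.from_product(grids, names=list(self.factor_levels)).to_frame(
            index=False
        )
        for col, mean in self.numeric_means.items():
            mesh[col] = mean
        X = self.encode(mesh)
        cells = mesh.groupby(factors, sort=True, observed=True).indices
        labels, rows = [], []
        for key, idx in cells.items():
            key = key if isinstance(key, tuple) else (key,)
            labels.append(key)
            rows.append(X[idx].mean(axis=0))
        grid = pd.DataFrame(labels, columns=factors)
        return grid, np.asarray(rows)


def _factor_columns(s: pd.Series, levels: list) -> tuple[np.ndarray, list[str]]:
    vals = np.asarray(s)
    cols = np.zeros((len(vals), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(vals == lev, 1.0, 0.0)
    cols[np.asarray(vals == levels[-1]), :] = -1.0
    names = [f"[{lev}]" for lev in levels[:-1]]
    return cols, names


def _encode(
    df: pd.DataFrame,
    terms: list[str],
    factor_levels: dict[str, list],
    numeric_means: dict[str, float],
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    n = len(df)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    term_slices: dict[str, np.ndarray] = {"Intercept": np.array([0])}
    for term in terms:
        parts = term.split(":")
        part_cols: list[tuple[np.ndarray, str]] = [(np.ones(n), "")]
        for part in parts:
            if part not in df.columns:
                raise KeyError(f"term component {part!r} not in table")
            if part in factor_levels:
                base, base_names = _factor_columns(df[part], factor_levels[part])
                new = [
                    (c * base[:, j], f"{nm}:{part}{base_names[j]}".lstrip(":"))
                    for c, nm in part_cols
                    for j in range(base.shape[1])
                ]
            else:
                x = df[part].to_numpy(dtype=float)
                new = [(c * x, f"{nm}:{part}".lstrip(":")) for c, nm in part_cols]
            part_cols = new
        idx0 = len(columns)
        for c, nm in part_cols:
            columns.append(c)
            names.append(nm)
        term_slices[term] = np.arange(idx0, len(columns))
    return np.column_stack(columns), names, term_slices


def build_design(df: pd.DataFrame, terms: list[str], check_rank: bool = True) -> Design:
    """Build an intercept-plus-terms design with sum-to-zero coding.

    ``terms`` are column names or ``a:b`` interactions; non-numeric columns
    are treated as factors.  Raises :class:`RankDeficientError` naming the
    aliased columns if the matrix is rank deficient.
    """
    factor_levels: dict[str, list] = {}
    numeric_means: dict[str, float] = {}
    for term in terms:
        for part in term.split(":"):
            if part in factor_levels or part in numeric_means:
                continue
            if part not in df.columns:
                raise KeyError(f"term component {part!r} not in table")
            if _is_factor(df[part]):
                levels = sorted(pd.unique(df[part]).tolist())
                if len(levels) < 2:
                    raise ValueError(f"factor {part!r} needs >= 2 levels")
                factor_levels[part] = levels
            else:
                numeric_means[part] = float(df[part].mean())
    X, names, term_slices = _encode(df, terms, factor_levels, numeric_means)
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, r = np.linalg.qr(X)
            aliased = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
            raise RankDeficientError(f"aliased fixed-effect columns: {aliased}")
    return Design(X, names, term_slices, factor_levels, numeric_means, list(terms))
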