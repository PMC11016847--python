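"""Sum-coded fixed-effect design matrices with term-level bookkeeping.

The ANOVA conventions used for the dormancy models (car-style type II
and type III Wald chi-square tests, and Tukey-adjusted contrasts of
estimated marginal means) need explicit control over which columns
belong to which model term and over the factor coding. This module
builds design matrices by hand:

* categorical factors use deviation (sum-to-zero) coding, under which a
  type III Wald test of a term's coefficient block is the conventional
  marginal test;
* continuous factors contribute caller-supplied numeric columns (e.g. an
  orthogonalised date polynomial contributes two);
* interaction terms are column-wise products of their parents' blocks.

Every build returns the matrix together with a ``{term: column-indices}``
map, so Wald block tests and marginal-mean contrasts never have to guess
column positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["Factor", "Design", "term_factors", "term_contains"]


@dataclass
class Factor:
    """One model factor: categorical (with levels) or continuous (with columns)."""

    name: str
    levels: Optional[List[str]] = None  # categorical iff not None
    columns: Optional[List[str]] = None  # data columns for continuous factors

    @property
    def is_categorical(self) -> bool:
        return self.levels is not None

    def n_cols(self) -> int:
        return len(self.levels) - 1 if self.is_categorical else len(self.columns)

    def encode(self, data: pd.DataFrame) -> np.ndarray:
        if self.is_categorical:
            vals = data[self.name].astype(str).to_numpy()
            unknown = set(vals) - set(self.levels)
            if unknown:
                raise ValueError(f"factor {self.name}: unknown level(s) {sorted(unknown)}")
            k = len(self.levels)
            out = np.zeros((len(vals), k - 1))
            for j, lev in enumerate(self.levels[:-1]):
                out[:, j] = (vals == lev).astype(float)
            out[vals == self.levels[-1], :] = -1.0
            return out
        return data[list(self.columns)].to_numpy(dtype=float)

    def colnames(self) -> List[str]:
        if self.is_categorical:
            return [f"{self.name}[S.{lev}]" for lev in self.levels[:-1]]
        return list(self.columns)


def term_factors(term: str) -> Tuple[str, ...]:
    """Factor names of a term string like ``"date:species"``."""
    return tuple(term.split(":"))


def term_contains(outer: str, inner: str) -> bool:
    """True when ``outer`` is a higher-order term containing ``inner``."""
    return outer != inner and set(term_factors(inner)) <= set(term_factors(outer))


class Design:
    """A fixed-effects design: a set of factors plus a list of terms.

    Terms are strings: factor names for main effects and colon-joined
    names for interactions (``"species:site"``). An intercept is always
    included under the term name ``"Intercept"``.
    """

    def __init__(self, factors: Sequence[Factor], terms: Sequence[str]):
        self.factors: Dict[str, Factor] = {f.name: f for f in factors}
        for t in terms:
            for fname in term_factors(t):
                if fname not in self.factors:
                    raise ValueError(f"term {t!r} references unknown factor {fname!r}")
        self.terms: List[str] = list(terms)

    def build(
        self, data: pd.DataFrame, terms: Optional[Sequence[str]] = None
    ) -> Tuple[np.ndarray, Dict[str, np.ndarray], List[str]]:
        """Build the design matrix for ``data``.

        Returns ``(X, slices, colnames)`` where ``slices[term]`` is the
        integer column index array of that term's block (including
        ``"Intercept"``).
        """
        terms = self.terms if terms is None else list(terms)
        blocks = [np.ones((len(data), 1))]
        names = ["Intercept"]
        slices: Dict[str, np.ndarray] = {"Intercept": np.array([0])}
        pos = 1
        encoded = {name: f.encode(data) for name, f in self.factors.items()}
        for t in terms:
            parts = term_factors(t)
            block = encoded[parts[0]]
            cn = self.factors[parts[0]].colnames()
            for p in parts[1:]:
                nxt = encoded[p]
                nxt_names = self.factors[p].colnames()
                block = np.einsum("ij,ik->ijk", block, nxt).reshape(len(data), -1)
                cn = [f"{a}:{b}" for a in cn for b in nxt_names]
            blocks.append(block)
            names.extend(cn)
            slices[t] = np.arange(pos, pos + block.shape[1])
            pos += block.shape[1]
        return np.concatenate(blocks, axis=1), slices, names

    # ------------------------------------------------------------------
    # estimated marginal means

    def reference_grid(self, data: pd.DataFrame) -> pd.DataFrame:
        """Cartesian grid over categorical levels, continuous at data means."""
        cats = [f for f in self.factors.values() if f.is_categorical]
        if cats:
            idx = pd.MultiIndex.from_product(
                [f.levels for f in cats], names=[f.name for f in cats]
            )
            grid = idx.to_frame(index=False)
        else:
            grid = pd.DataFrame({"_": [0]})
        for f in self.factors.values():
            if not f.is_categorical:
                for c in f.columns:
                    grid[c] = float(data[c].mean())
        return grid

    def emm_rows(
        self, data: pd.DataFrame, factor: str, terms: Optional[Sequence[str]] = None
    ) -> Tuple[np.ndarray, List[str]]:
        """Linear-combination rows giving each level's estimated marginal mean.

        Each row averages the design over the reference grid holding the
        target factor at one level, so ``L @ beta`` is the vector of EMMs
        on the linear-predictor scale.
        """
        f = self.factors[factor]
        if not f.is_categorical:
            raise ValueError(f"{factor} is not a categorical factor")
        grid = self.reference_grid(data)
        X, _, _ = self.build(grid, terms)
        L = np.vstack(
            [X[(grid[factor] == lev).to_numpy()].mean(axis=0) for lev in f.levels]
        )
        return L, list(f.levels)
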