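"""BDeu marginal likelihood for discrete data, intervention-aware.

For multinomial conditionals with independent Dirichlet parameter priors the
marginal likelihood P(D|G) has a closed form that decomposes over families
(a child together with its parent set):

    log P(D|G) = sum_i sum_j [ log G(a_ij) - log G(a_ij + N_ij)
                 + sum_k ( log G(a_ijk + N_ijk) - log G(a_ijk) ) ]

where j indexes joint parent configurations, k child states, N_ijk the
observed counts and G the gamma function.  BDeu hyperparameters divide an
equivalent sample size uniformly: a_ijk = ess / (r_i * q_i) with r_i the
child arity and q_i the number of parent configurations; this makes the
score equal across Markov-equivalent DAGs on observational data.

Interventional samples are handled by masking (Cooper-Yoo): a value that was
experimentally clamped is excluded from the counts of its own family but
still conditions its children, which is what breaks score equivalence and
lets the data orient edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dag import ADDITION, DELETION, DagStructure, EdgeMove


@dataclass
class DiscreteDataset:
    """Integer-coded discrete observations.

    Attributes
    ----------
    values
        ``(n_samples, n_variables)`` integer matrix with codes in
        ``0 .. arity-1`` per column.
    arities
        Per-variable category counts (each >= 2).
    intervention_mask
        Optional boolean matrix of the same shape; True marks a value that
        was set by perturbation rather than observed.
    variable_names
        Optional column labels.
    """

    values: np.ndarray
    arities: np.ndarray
    intervention_mask: Optional[np.ndarray] = None
    variable_names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variables)")
        self.arities = np.asarray(self.arities, dtype=np.int64)
        if self.arities.shape != (self.values.shape[1],):
            raise ValueError("arities must have one entry per variable")
        if np.any(self.arities < 2):
            raise ValueError("all arities must be >= 2")
        if self.values.size and (
            self.values.min() < 0 or np.any(self.values.max(axis=0) >= self.arities)
        ):
            raise ValueError("values must lie in 0..arity-1 per column")
        if self.intervention_mask is not None:
            self.intervention_mask = np.asarray(self.intervention_mask, dtype=bool)
            if self.intervention_mask.shape != self.values.shape:
                raise ValueError("intervention mask shape must match values")
        if self.variable_names is not None:
            self.variable_names = tuple(self.variable_names)
            if len(self.variable_names) != self.values.shape[1]:
                raise ValueError("variable_names length must match columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        mask: Optional[pd.DataFrame] = None,
        arities: Optional[Sequence[int]] = None,
    ) -> "DiscreteDataset":
        values = frame.to_numpy(dtype=np.int64)
        if arities is None:
            if values.size == 0:
                raise ValueError("cannot infer arities from an empty table")
            arities = values.max(axis=0) + 1
            arities = np.maximum(arities, 2)
        mask_arr = None
        if mask is not None:
            mask_arr = mask.to_numpy().astype(bool)
        return cls(values, np.asarray(arities), mask_arr, tuple(map(str, frame.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.variable_names or [f"X{i}" for i in range(self.n_variables)]
        return pd.DataFrame(self.values, columns=list(cols))


@dataclass
class ScoreSettings:
    """Hyperparameters of the structure score.

    ``equivalent_sample_size`` scales the Dirichlet prior (BDeu); the
    structure prior is uniform by default — ``log_structure_prior`` is a hook
    taking a :class:`DagStructure` and returning an (unnormalized) log prior.
    """

    equivalent_sample_size: float = 1.0
    log_structure_prior: Optional[Callable[[DagStructure], float]] = None
    cache_max_entries: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.equivalent_sample_size > 0:
            raise ValueError("equivalent_sample_size must be positive")

    def log_prior(self, dag: DagStructure) -> float:
        if self.log_structure_prior is None:
            return 0.0
        return float(self.log_structure_prior(dag))


class BDeuScorer:
    """Family-cached BDeu scorer bound to one dataset.

    The cache is keyed on ``(child, sorted parent tuple)``; both the full
    graph score and the delta score of a single move go through it, so a
    Markov chain rescoring mostly-unchanged graphs costs a handful of
    dictionary lookups per step.
    """

    def __init__(self, dataset: DiscreteDataset, settings: Optional[ScoreSettings] = None):
        self.dataset = dataset
        self.settings = settings or ScoreSettings()
        self._cache: dict[tuple, float] = {}
        # per-column row selector excluding intervened values of that column
        mask = dataset.intervention_mask
        self._keep: Optional[list[np.ndarray]] = None
        if mask is not None and mask.any():
            self._keep = [np.nonzero(~mask[:, j])[0] for j in range(dataset.n_variables)]

    # ------------------------------------------------------------------
    def family_log_score(self, child: int, parents: Sequence[int]) -> float:
        """Log Dirichlet-multinomial marginal of one family.

        Samples where the child itself was intervened on are excluded from
        the counts.  Zero usable samples give log 1 = 0.
        """
        parents = tuple(sorted(int(p) for p in parents))
        nvar = self.dataset.n_variables
        if not (0 <= child < nvar):
            raise ValueError(f"invalid child {child}")
        if any(not (0 <= p < nvar) for p in parents):
            raise ValueError(f"invalid parent in {parents}")
        if child in parents:
            raise ValueError("child cannot be its own parent")
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        value = self._compute_family(child, parents)
        limit = self.settings.cache_max_entries
        if limit is None or len(self._cache) < limit:
            self._cache[key] = value
        return value

    def _compute_family(self, child: int, parents: tuple[int, ...]) -> float:
        data = self.dataset.values
        arities = self.dataset.arities
        if self._keep is not None:
            rows = self._keep[child]
            data = data[rows]
        if data.shape[0] == 0:
            return 0.0
        r = int(arities[child])
        q = int(np.prod(arities[list(parents)])) if parents else 1
        ess = self.settings.equivalent_sample_size
        alpha_jk = ess / (r * q)
        alpha_j = ess / q

        child_col = data[:, child]
        if parents:
            codes = np.zeros(data.shape[0], dtype=np.int64)
            for p in parents:  # mixed-radix parent configuration index
                codes = codes * arities[p] + data[:, p]
            cell = codes * r + child_col
            counts = np.bincount(cell, minlength=q * r).reshape(q, r)
        else:
            counts = np.bincount(child_col, minlength=r).reshape(1, r)

        n_j = counts.sum(axis=1)
        nonzero = n_j > 0
        counts = counts[nonzero]
        n_j = n_j[nonzero]
        score = float(
            np.sum(gammaln(alpha_j) - gammaln(alpha_j + n_j))
            + np.sum(gammaln(alpha_jk + counts) - gammaln(alpha_jk))
        )
        return score

    # ------------------------------------------------------------------
    def graph_log_score(self, dag: DagStructure) -> float:
        """log P(D|G): sum of family scores over all nodes."""
        if dag.n_nodes != self.dataset.n_variables:
            raise ValueError(
                f"dag has {dag.n_nodes} nodes but dataset has "
                f"{self.dataset.n_variables} variables"
            )
        adj = dag.adjacency
        total = 0.0
        for child in range(dag.n_nodes):
            parents = tuple(np.nonzero(adj[:, child])[0].tolist())
            total += self.family_log_score(child, parents)
        return total

    def delta_log_score(self, dag: DagStructure, move: EdgeMove) -> float:
        """Score difference of applying ``move``, rescoring only the
        affected families (one for add/delete, two for reversal)."""
        u, v = move.edge
        adj = dag.adjacency
        if move.kind == ADDITION:
            if adj[u, v]:
                raise ValueError("move inapplicable: edge already present")
            old_p = tuple(np.nonzero(adj[:, v])[0].tolist())
            new_p = tuple(sorted(old_p + (u,)))
            return self.family_log_score(v, new_p) - self.family_log_score(v, old_p)
        if not adj[u, v]:
            raise ValueError("move inapplicable: edge absent")
        old_pv = tuple(np.nonzero(adj[:, v])[0].tolist())
        new_pv = tuple(p for p in old_pv if p != u)
        delta = self.family_log_score(v, new_pv) - self.family_log_score(v, old_pv)
        if move.kind == DELETION:
            return delta
        old_pu = tuple(np.nonzero(adj[:, u])[0].tolist())
        new_pu = tuple(sorted(old_pu + (v,)))
        delta += self.family_log_score(u, new_pu) - self.family_log_score(u, old_pu)
        return delta

    def log_posterior(self, dag: DagStructure) -> float:
        """Unnormalized log posterior: log P(D|G) + log P(G)."""
        return self.graph_log_score(dag) + self.settings.log_prior(dag)

    @property
    def cache_size(self) -> int:
        return len(self._cache)


# convenience functional surface ------------------------------------------------

def family_log_score(
    child: int,
    parents: Sequence[int],
    dataset: DiscreteDataset,
    settings: Optional[ScoreSettings] = None,
) -> float:
    return BDeuScorer(dataset, settings).family_log_score(child, parents)


def graph_log_score(
    dag: DagStructure,
    dataset: DiscreteDataset,
    settings: Optional[ScoreSettings] = None,
) -> float:
    return BDeuScorer(dataset, settings).graph_log_score(dag)


def delta_log_score(
    dag: DagStructure,
    move: EdgeMove,
    dataset: DiscreteDataset,
    settings: Optional[ScoreSettings] = None,
) -> float:
    return BDeuScorer(dataset, settings).delta_log_score(dag, move)
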