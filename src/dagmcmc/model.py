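"""Model/results front end.

:class:`StructureMCMC` is built from a discrete dataset and a run protocol;
``fit()`` runs an ensemble of Metropolis-Hastings chains and returns a
:class:`StructureMCMCResults` carrying the retained samples, pooled edge
posteriors, MAP structure, acceptance bookkeeping and convergence
diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .dag import DagStructure
from .exact import exact_edge_posteriors, exact_posterior
from .proposal import ProposalSpec
from .sampler import ChainConfig, ChainSample, pool_samples, run_chain_ensemble
from .scoring import DiscreteDataset, ScoreSettings


class StructureMCMC:
    """Bayesian-network structure sampler over a discrete dataset.

    Parameters
    ----------
    data
        A :class:`DiscreteDataset` or an integer-coded DataFrame/array.
    intervention_mask
        Optional same-shape 0/1 mask (True/1 = value was clamped by a
        perturbation, not observed).
    proposal
        Mixture vector ``[p_1, ..., p_max]`` over transition lengths; the
        classical single-edge-change proposal is ``(1.0,)``.
    max_fanin
        Optional cap on the number of parents per node.
    ess
        Equivalent sample size of the BDeu prior.
    """

    def __init__(
        self,
        data: Union[DiscreteDataset, pd.DataFrame, np.ndarray],
        intervention_mask: Optional[np.ndarray] = None,
        proposal: Sequence[float] = (0.8, 0.2),
        max_fanin: Optional[int] = None,
        ess: float = 1.0,
        arities: Optional[Sequence[int]] = None,
    ) -> None:
        if isinstance(data, DiscreteDataset):
            self.dataset = data
        elif isinstance(data, pd.DataFrame):
            mask_df = (
                pd.DataFrame(intervention_mask) if intervention_mask is not None else None
            )
            self.dataset = DiscreteDataset.from_dataframe(data, mask_df, arities)
        else:
            values = np.asarray(data, dtype=np.int64)
            if arities is None:
                arities = np.maximum(values.max(axis=0) + 1, 2)
            self.dataset = DiscreteDataset(
                values, np.asarray(arities), intervention_mask
            )
        if isinstance(proposal, ProposalSpec):
            self.proposal = proposal
        else:
            self.proposal = ProposalSpec(tuple(proposal), max_fanin)
        self.score_settings = ScoreSettings(equivalent_sample_size=ess)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, mask: Optional[pd.DataFrame] = None, **kwargs
    ) -> "StructureMCMC":
        mask_arr = mask.to_numpy().astype(bool) if mask is not None else None
        return cls(frame, intervention_mask=mask_arr, **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        burn_in: int = 10_000,
        sample_size: int = 10_000,
        thin: int = 1,
        chains: int = 4,
        seed: int = 0,
        initial_dag: Union[DagStructure, str] = "random",
    ) -> "StructureMCMCResults":
        """Run ``chains`` independent chains with per-chain derived seeds."""
        seeds = np.random.SeedSequence(seed).generate_state(chains) % (2**31)
        configs = [
            ChainConfig(
                proposal=self.proposal,
                burn_in=burn_in,
                sample_size=sample_size,
                thin=thin,
                seed=int(s),
                initial_dag=initial_dag,
                score=self.score_settings,
            )
            for s in seeds
        ]
        samples = run_chain_ensemble(configs, self.dataset)
        return StructureMCMCResults(self, samples)

    def exact_results(self) -> tuple[np.ndarray, "object"]:
        """Exact edge posteriors by enumeration (n <= 6 only): the oracle
        the sampled estimates can be checked against."""
        dist = exact_posterior(
            self.dataset, self.score_settings, self.proposal.max_fanin
        )
        return exact_edge_posteriors(dist), dist


class StructureMCMCResults:
    """Posterior sample over structures with diagnostics.

    Attributes
    ----------
    chains
        Per-chain :class:`ChainSample` objects.
    pooled
        All retained states concatenated.
    """

    def __init__(self, model: StructureMCMC, chains: list[ChainSample]):
        self.model = model
        self.chains = chains
        self.pooled = pool_samples(chains)
        self._edge_posteriors: Optional[diag.EdgePosteriorMatrix] = None

    # -- estimates ------------------------------------------------------
    @property
    def edge_posteriors(self) -> diag.EdgePosteriorMatrix:
        """Pooled posterior probability of each directed edge."""
        if self._edge_posteriors is None:
            self._edge_posteriors = diag.edge_posteriors(self.pooled)
        return self._edge_posteriors

    def edge_posteriors_frame(self) -> pd.DataFrame:
        names = self.model.dataset.variable_names or [
            f"X{i}" for i in range(self.model.dataset.n_variables)
        ]
        return pd.DataFrame(self.edge_posteriors.values, index=names, columns=names)

    @property
    def map_dag(self) -> DagStructure:
        return diag.map_dag(self.pooled)[0]

    @property
    def map_score(self) -> float:
        return diag.map_dag(self.pooled)[1]

    def consensus_graph(self, threshold: float = 0.85) -> diag.ConsensusGraph:
        return diag.consensus_graph(self.edge_posteriors, threshold)

    # -- diagnostics ----------------------------------------------------
    def pairwise_ssd(self) -> np.ndarray:
        return diag.pairwise_ssd_matrix(self.chains)

    def mean_pairwise_ssd(self) -> float:
        return diag.mean_pairwise_ssd(self.chains)

    def best_converged_pair(self) -> tuple[tuple[int, int], float]:
        return diag.best_converged_pair(self.chains)

    def unique_dag_counts(self) -> list[int]:
        return [diag.unique_dag_count(c) for c in self.chains]

    def acceptance_rates(self) -> list[float]:
        return [c.acceptance_rate for c in self.chains]

    def score_trace(self, chain: int = 0, last_k: Optional[int] = None) -> np.ndarray:
        return diag.score_trace(self.chains[chain], last_k)

    def plot_score_traces(self, last_k: Optional[int] = None, ax=None):
        """Score traces of all chains on one axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, c in enumerate(self.chains):
            tr = diag.score_trace(c, last_k)
            ax.plot(tr[:, 0], tr[:, 1], lw=0.7, label=f"chain {i}")
        ax.set_xlabel("retained state")
        ax.set_ylabel("log score")
        ax.legend(fontsize="small")
        return ax

    # -- reporting ------------------------------------------------------
    def summary(self, edge_threshold: float = 0.5) -> str:
        """Plain-text report: run protocol, per-chain diagnostics, MAP
        score and the edges above ``edge_threshold`` posterior."""
        m = self.model
        names = m.dataset.variable_names or [
            f"X{i}" for i in range(m.dataset.n_variables)
        ]
        lines = []
        lines.append("Structure MCMC results")
        lines.append("=" * 58)
        lines.append(
            f"variables: {m.dataset.n_variables}   samples: {m.dataset.n_samples}"
            f"   interventions: "
            f"{int(m.dataset.intervention_mask.sum()) if m.dataset.intervention_mask is not None else 0}"
        )
        lines.append(
            f"proposal [p_1..p_max]: {list(m.proposal.length_probs)}"
            f"   max fan-in: {m.proposal.max_fanin}"
            f"   ESS: {m.score_settings.equivalent_sample_size}"
        )
        cfg = self.chains[0].config
        lines.append(
            f"chains: {len(self.chains)}   burn-in: {cfg.burn_in}"
            f"   sample: {cfg.sample_size}   thin: {cfg.thin}"
        )
        lines.append("-" * 58)
        lines.append("chain   accept-rate   unique DAGs   mean log score")
        for i, c in enumerate(self.chains):
            lines.append(
                f"{i:>5}   {c.acceptance_rate:>11.3f}   "
                f"{diag.unique_dag_count(c):>11}   {float(np.mean(c.log_scores)):>14.3f}"
            )
        if len(self.chains) >= 2:
            pair, ssd = self.best_converged_pair()
            lines.append(
                f"mean pairwise edge-posterior SSD: {self.mean_pairwise_ssd():.4f}"
                f"   best pair: {pair} (SSD {ssd:.4f})"
            )
        lines.append(f"MAP log score: {self.map_score:.4f}")
        lines.append("-" * 58)
        lines.append(f"edges with posterior > {edge_threshold}:")
        ep = self.edge_posteriors.values
        rows = [
            (names[u], names[v], ep[u, v])
            for u, v in zip(*np.nonzero(ep > edge_threshold))
        ]
        if rows:
            for pu, pv, p in sorted(rows, key=lambda r: -r[2]):
                lines.append(f"  {pu} -> {pv}   {p:.3f}")
        else:
            lines.append("  (none)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<StructureMCMCResults: {len(self.chains)} chains x "
            f"{len(self.chains[0])} states>"
        )
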