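"""Dataset I/O, run manifests and experiment orchestration.

File conventions: datasets are TSV/CSV with a header row of variable names
and non-negative integer cells; the optional intervention mask is a
same-shape 0/1 table; nodes are 0-indexed and edges written parent->child.
Every run directory carries a ``manifest.json`` snapshot (config, seeds,
acceptance rates, input digests) sufficient to reproduce the retained DAG
sequences bit-identically on the same platform.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dag import write_edge_list, to_dot
from .diagnostics import (
    best_converged_pair,
    edge_posteriors,
    map_dag,
    mean_pairwise_ssd,
    pairwise_ssd_matrix,
    unique_dag_count,
)
from .proposal import ProposalSpec
from .sampler import ChainConfig, ChainSample, pool_samples, run_chain_ensemble
from .scoring import DiscreteDataset, ScoreSettings


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] == 1 and sep == "\t":
        frame = pd.read_csv(path, sep=",")
    return frame


def read_dataset(
    path,
    mask_path=None,
    arities: Optional[Sequence[int]] = None,
) -> DiscreteDataset:
    """Read a dataset table (TSV or CSV, header row) and optional mask.

    Cells must be non-negative integers; arities default to (max code + 1)
    per column.
    """
    frame = _read_table(path)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        try:
            as_float = values.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {path}") from exc
        if not np.all(as_float == np.floor(as_float)):
            raise ValueError(f"non-integer cell in {path}")
        frame = frame.astype(int)
    if (frame.to_numpy() < 0).any():
        raise ValueError(f"negative value in {path}")
    mask_frame = None
    if mask_path is not None:
        mask_frame = _read_table(mask_path)
        if mask_frame.shape != frame.shape:
            raise ValueError(
                f"mask shape {mask_frame.shape} does not match data shape {frame.shape}"
            )
    return DiscreteDataset.from_dataframe(frame, mask_frame, arities)


def write_dataset(dataset: DiscreteDataset, path, mask_path=None) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    dataset.to_dataframe().to_csv(path, sep=sep, index=False)
    if mask_path is not None and dataset.intervention_mask is not None:
        cols = dataset.variable_names or [f"X{i}" for i in range(dataset.n_variables)]
        pd.DataFrame(
            dataset.intervention_mask.astype(int), columns=list(cols)
        ).to_csv(mask_path, sep="\t", index=False)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# run output
# ---------------------------------------------------------------------------

def write_chain_outputs(
    out_dir, samples: list[ChainSample], manifest_extra: Optional[dict] = None,
    input_files: Sequence = (),
) -> dict:
    """Write per-run artifacts under ``out_dir``:

    - ``dags_<i>.txt.gz``: one edge-list string per retained state
    - ``trace_<i>.csv``: (step, log_score)
    - ``edge_posteriors_<i>.csv`` and pooled ``edge_posteriors.csv``
    - ``manifest.json``
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        with gzip.open(out / f"dags_{i}.txt.gz", "wt") as fh:
            for g in s.dags:
                fh.write(";".join(f"{u},{v}" for u, v in g.sorted_edges()) + "\n")
        trace = pd.DataFrame(
            {"step": np.arange(len(s)), "log_score": s.log_scores}
        )
        trace.to_csv(out / f"trace_{i}.csv", index=False)
        np.savetxt(
            out / f"edge_posteriors_{i}.csv",
            edge_posteriors(s).values,
            delimiter=",",
            fmt="%.6f",
        )
    pooled = pool_samples(samples)
    np.savetxt(
        out / "edge_posteriors.csv",
        edge_posteriors(pooled).values,
        delimiter=",",
        fmt="%.6f",
    )
    g_map, score = map_dag(pooled)
    write_edge_list(g_map, out / "map_dag.tsv")
    (out / "map_dag.dot").write_text(to_dot(g_map))
    cfg0 = samples[0].config
    manifest = {
        "software_version": __version__,
        "config": {
            "proposal": list(cfg0.proposal.length_probs),
            "max_fanin": cfg0.proposal.max_fanin,
            "burn_in": cfg0.burn_in,
            "sample_size": cfg0.sample_size,
            "thin": cfg0.thin,
            "ess": cfg0.score.equivalent_sample_size,
        },
        "chain_seeds": [s.config.seed for s in samples],
        "acceptance_rates": [s.acceptance_rate for s in samples],
        "unique_dags": [unique_dag_count(s) for s in samples],
        "map_log_score": score,
        "input_digests": {str(p): _digest(p) for p in input_files},
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_chain_configs(
    proposal: ProposalSpec,
    chains: int,
    burn_in: int,
    sample_size: int,
    thin: int,
    seed: int,
    ess: float = 1.0,
    initial_dag="random",
) -> list[ChainConfig]:
    """Derive per-chain configs with independent seeds below 2**31."""
    seeds = np.random.SeedSequence(seed).generate_state(chains) % (2**31)
    score = ScoreSettings(equivalent_sample_size=ess)
    return [
        ChainConfig(
            proposal=proposal,
            burn_in=burn_in,
            sample_size=sample_size,
            thin=thin,
            seed=int(s),
            initial_dag=initial_dag,
            score=score,
        )
        for s in seeds
    ]


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def experiment_runner(config: dict, out_dir) -> dict:
    """Run a multi-proposal, multi-chain sweep.

    ``config`` keys::

        data: path to dataset TSV/CSV        (or)
        generator: {nodes, density, arity, concentration, samples,
                    interventions, seed}
        proposals: list of proposal vectors, e.g. [[1.0], [0.8, 0.2]]
        chains, burn_in, sample_size, thin, fanin, ess, seed
        subsample_sizes: optional list of dataset sizes to sweep

    For every (proposal, dataset size) cell an ensemble is run and written
    to its own run directory; a ``summary.csv`` collects mean pairwise SSD,
    best-pair SSD and MAP score per cell.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    input_files = []
    if "data" in config:
        dataset = read_dataset(config["data"], config.get("mask"))
        input_files.append(config["data"])
        if config.get("mask"):
            input_files.append(config["mask"])
    elif "generator" in config:
        from .synthetic import interventional_sample, random_bn

        g = config["generator"]
        rng = np.random.default_rng(int(g.get("seed", seed)))
        bn = random_bn(
            int(g["nodes"]),
            float(g.get("density", 0.3)),
            int(g.get("arity", 3)),
            float(g.get("concentration", 0.5)),
            config.get("fanin"),
            rng,
        )
        dataset = interventional_sample(
            bn, int(g["samples"]), float(g.get("interventions", 0.0)), rng
        )
        (out / "ground_truth_bn.json").write_text(bn.to_json())
    else:
        raise ValueError("experiment config needs 'data' or 'generator'")

    proposals = config.get("proposals")
    if not proposals:
        raise ValueError("experiment config needs a non-empty 'proposals' list")
    fanin = config.get("fanin")
    chains = int(config.get("chains", 3))
    burn_in = int(config.get("burn_in", 10_000))
    sample_size = int(config.get("sample_size", 10_000))
    thin = int(config.get("thin", 1))
    ess = float(config.get("ess", 1.0))
    sizes = config.get("subsample_sizes") or [dataset.n_samples]

    rows = []
    rng = np.random.default_rng(seed + 1)
    for size in sizes:
        size = int(size)
        if size > dataset.n_samples:
            raise ValueError(f"subsample size {size} exceeds dataset size")
        if size == dataset.n_samples:
            sub = dataset
        else:
            idx = rng.permutation(dataset.n_samples)[:size]
            sub = DiscreteDataset(
                dataset.values[idx],
                dataset.arities.copy(),
                None
                if dataset.intervention_mask is None
                else dataset.intervention_mask[idx],
                dataset.variable_names,
            )
        for p_idx, vec in enumerate(proposals):
            spec = ProposalSpec(tuple(float(x) for x in vec), fanin)
            cfgs = make_chain_configs(
                spec, chains, burn_in, sample_size, thin,
                seed + 1000 * p_idx + size, ess,
            )
            samples = run_chain_ensemble(cfgs, sub)
            run_dir = out / f"run_p{p_idx}_n{size}"
            write_chain_outputs(
                run_dir,
                samples,
                {"proposal_index": p_idx, "dataset_size": size},
                input_files,
            )
            pooled = pool_samples(samples)
            _, map_score = map_dag(pooled)
            row = {
                "proposal": ",".join(str(x) for x in vec),
                "dataset_size": size,
                "chains": chains,
                "mean_pairwise_ssd": mean_pairwise_ssd(samples)
                if chains >= 2
                else np.nan,
                "best_pair_ssd": best_converged_pair(samples)[1]
                if chains >= 2
                else np.nan,
                "map_log_score": map_score,
                "mean_acceptance": float(
                    np.mean([s.acceptance_rate for s in samples])
                ),
                "run_dir": run_dir.name,
            }
            rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    return {"summary": summary, "out_dir": str(out)}
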