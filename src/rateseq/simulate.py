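"""Synthetic labeled-RNA-seq time series with known kinetic truth.

The generator emulates what a pull-down of thiolated RNA sequences: each
library contains the labeled fraction of every transcript plus the
constant-mass spike-ins.  Expected labeled molecules per transcript follow
the saturating-exponential labeling curve; the library is a compositional
sample of fixed read depth over those molecules, and per-feature counts are
drawn negative-binomially around their compositional expectation
(overdispersed, as real count data are).  Because spike-in mass is constant
while the labeled pool grows, the spike-ins' read share declines over time
as the transcriptome's share rises.

Defaults reflect the study conditions this simulator emulates: two
replicates sampled at 3/5/7/11/13/25 min and 5/7/9/13/20/25/30/100 min
after label addition, half-lives log-uniform on 2–60 min, a 100-min
doubling time, a 2-min detection delay, three spike-ins, and gene-count NB
size 10.  Spike-in counts get a tighter NB size (default 100): they are a
technical control carrying pipetting/capture noise, not biological
variability, and the deviance detector relies on their ratios being stable.
Depth defaults to 2e6 reads per library.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CountMatrix, RunConfig
from .kinetics import LN2, alpha_growth_from_doubling, model_y

__all__ = [
    "SimTruth",
    "SimDataset",
    "default_designs",
    "make_truth",
    "simulate",
    "expected_fractions",
    "inject_artifact",
    "make_recovery_suite",
]


def default_designs() -> dict[str, list[float]]:
    """The two replicate time-point designs (minutes after label addition)."""
    return {
        "rep1": [3.0, 5.0, 7.0, 11.0, 13.0, 25.0],
        "rep2": [5.0, 7.0, 9.0, 13.0, 20.0, 25.0, 30.0, 100.0],
    }


@dataclass
class SimTruth:
    """Ground truth behind a simulated dataset."""

    transcript_ids: list[str]
    alpha_rna: np.ndarray  # per minute
    y_eq: np.ndarray  # equilibrium labeled molecules, arbitrary units
    dispersion: float  # NB size for gene counts
    spikein_dispersion: float  # NB size for spike-in counts
    alpha_growth: float
    t_d: float
    designs: dict[str, list[float]]
    spikein_molecules: dict[str, float]
    depth: float
    rng_seed: int
    lengths_nt: dict[str, int] = field(default_factory=dict)
    terms: dict[str, list[str]] | None = None
    artifacts: list[tuple[str, float, str, float]] = field(default_factory=list)

    @property
    def alpha_total(self) -> np.ndarray:
        return self.alpha_rna + self.alpha_growth

    @property
    def half_life(self) -> np.ndarray:
        return LN2 / self.alpha_rna


@dataclass
class SimDataset:
    counts: CountMatrix
    truth: SimTruth


def make_truth(
    n_transcripts: int,
    seed: int,
    half_life_range: tuple[float, float] = (2.0, 60.0),
    doubling_time: float = 100.0,
    t_d: float = 2.0,
    depth: float = 2e6,
    dispersion: float = 10.0,
    spikein_dispersion: float = 100.0,
    n_spikeins: int = 3,
    spike_fraction_start: float = 0.3,
    designs: dict[str, list[float]] | None = None,
    length_bias_exponent: float = 0.0,
) -> SimTruth:
    """Draw per-transcript truth and size the spike-ins.

    Half-lives are log-uniform over ``half_life_range``; equilibrium
    abundances are log-normal (arbitrary units).  Spike-in total molecules
    are set so the spike-ins' expected read share is
    ``spike_fraction_start`` at the earliest time point, split 1:2:4 among
    the spike-ins; it then declines as labeling accumulates.  A nonzero
    ``length_bias_exponent`` multiplies Y_eq (never alpha) by
    (length/1200)^exponent, mimicking preferential labeling of long
    transcripts, which shifts equilibrium levels but not decay estimates.
    """
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    ids = [f"gene{i:04d}" for i in range(n_transcripts)]
    lo, hi = half_life_range
    hl = np.exp(rng.uniform(np.log(lo), np.log(hi), n_transcripts))
    alpha_rna = LN2 / hl
    y_eq = np.exp(rng.normal(0.0, 1.0, n_transcripts))
    lengths = {g: int(l) for g, l in zip(ids, np.exp(rng.normal(np.log(1200), 0.4, n_transcripts)))}
    if length_bias_exponent:
        fac = np.array([(lengths[g] / 1200.0) ** length_bias_exponent for g in ids])
        y_eq = y_eq * fac
    designs = designs if designs is not None else default_designs()
    alpha_growth = alpha_growth_from_doubling(doubling_time)

    t_first = min(min(ts) for ts in designs.values())
    labeled_first = float(
        np.sum(model_y(t_first, alpha_rna + alpha_growth, y_eq, t_d))
    )
    if not 0 < spike_fraction_start < 1:
        raise ValueError("spike_fraction_start must be in (0, 1)")
    s_total = labeled_first * spike_fraction_start / (1.0 - spike_fraction_start)
    weights = np.array([2.0**i for i in range(n_spikeins)])
    weights /= weights.sum()
    spikes = {f"spike{i + 1}": float(s_total * w) for i, w in enumerate(weights)}
    for i, sid in enumerate(spikes):
        lengths[sid] = 1000 + 200 * i
    return SimTruth(
        transcript_ids=ids,
        alpha_rna=alpha_rna,
        y_eq=y_eq,
        dispersion=dispersion,
        spikein_dispersion=spikein_dispersion,
        alpha_growth=alpha_growth,
        t_d=t_d,
        designs=designs,
        spikein_molecules=spikes,
        depth=depth,
        rng_seed=seed,
        lengths_nt=lengths,
    )


def _expected_molecules(truth: SimTruth, t: float) -> np.ndarray:
    """Labeled gene molecules then spike-in molecules at time t."""
    if t <= truth.t_d:
        genes = np.zeros_like(truth.y_eq)
    else:
        genes = truth.y_eq * -np.expm1(-truth.alpha_total * (t - truth.t_d))
    spikes = np.array(list(truth.spikein_molecules.values()))
    return np.concatenate([genes, spikes])


def expected_fractions(truth: SimTruth, replicate: str) -> pd.DataFrame:
    """Expected read fraction of every feature at each time point (columns)."""
    ids = truth.transcript_ids + list(truth.spikein_molecules)
    cols = {}
    for t in truth.designs[replicate]:
        mol = _expected_molecules(truth, t)
        cols[t] = mol / mol.sum()
    return pd.DataFrame(cols, index=ids)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if np.isinf(size):
        return rng.poisson(mu)
    p = size / (size + mu)  # mu = 0 -> p = 1 -> count 0
    return rng.negative_binomial(size, p)


def simulate(truth: SimTruth) -> SimDataset:
    """Draw one dataset from the truth; deterministic given the seed."""
    rng = np.random.default_rng(truth.rng_seed)
    n_genes = len(truth.transcript_ids)
    spike_ids = list(truth.spikein_molecules)
    low_spike = min(truth.spikein_molecules.values())
    columns = []
    data = []
    for rep in truth.designs:
        for t in truth.designs[rep]:
            mol = _expected_molecules(truth, t)
            frac = mol / mol.sum()
            mu = truth.depth * frac
            if mu[n_genes:].min() < 10:
                warnings.warn(
                    f"depth {truth.depth:g} leaves a spike-in under 10 expected "
                    f"reads at {rep} t={t:g}",
                    stacklevel=2,
                )
            counts = np.empty(len(mol), dtype=np.int64)
            counts[:n_genes] = _nb_draw(rng, mu[:n_genes], truth.dispersion)
            counts[n_genes:] = _nb_draw(rng, mu[n_genes:], truth.spikein_dispersion)
            columns.append((rep, t))
            data.append(counts)
    mat = pd.DataFrame(
        np.column_stack(data),
        index=truth.transcript_ids + spike_ids,
        columns=pd.MultiIndex.from_tuples(columns, names=["replicate", "time_min"]),
    )
    lengths = {s: truth.lengths_nt.get(s, 0) for s in spike_ids}
    cm = CountMatrix(counts=mat, spikein_ids=spike_ids, spikein_lengths=lengths)
    return SimDataset(counts=cm, truth=truth)


def inject_artifact(
    ds: SimDataset, timepoint: float, spikein: str, fold: float, replicate: str | None = None
) -> SimDataset:
    """Scale one spike-in's count by ``fold`` at one time point.

    Applies to every replicate measuring that time point unless
    ``replicate`` narrows it.  Returns a new dataset; the injection is
    recorded in the truth so tests can assert against it.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if spikein not in ds.counts.spikein_ids:
        raise ValueError(f"unknown spike-in {spikein!r}")
    reps = [replicate] if replicate is not None else ds.counts.replicates
    mat = ds.counts.counts.copy()
    truth = dataclasses.replace(ds.truth, artifacts=list(ds.truth.artifacts))
    hit = False
    for rep in reps:
        if (rep, timepoint) in mat.columns:
            mat.loc[spikein, (rep, timepoint)] = int(
                round(mat.loc[spikein, (rep, timepoint)] * fold)
            )
            truth.artifacts.append((rep, timepoint, spikein, fold))
            hit = True
    if not hit:
        raise ValueError(f"time point {timepoint} not present in replicates {reps}")
    cm = CountMatrix(
        counts=mat,
        spikein_ids=list(ds.counts.spikein_ids),
        spikein_lengths=dict(ds.counts.spikein_lengths),
    )
    return SimDataset(counts=cm, truth=truth)


def make_recovery_suite(
    n_transcripts: int, seed: int, outdir=None, **truth_kwargs
) -> SimDataset:
    """Simulate a parameter-recovery dataset, optionally writing it to disk.

    With ``outdir`` set, writes counts.tsv, spikeins.tsv, config.yaml (run
    parameters plus the column layout) and truth.tsv — the same formats the
    pipeline reads, byte-identical across re-runs with the same arguments.
    """
    if n_transcripts < 10:
        raise ValueError("recovery suites need at least 10 transcripts")
    truth = make_truth(n_transcripts, seed, **truth_kwargs)
    ds = simulate(truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        colname = lambda rep, t: f"{rep}_t{t:g}"
        out = ds.counts.counts.copy()
        out.columns = [colname(r, t) for r, t in out.columns]
        out.index.name = "transcript_id"
        out.to_csv(outdir / "counts.tsv", sep="\t")
        pd.DataFrame(
            {"id": list(truth.spikein_molecules),
             "length_nt": [truth.lengths_nt[s] for s in truth.spikein_molecules]}
        ).to_csv(outdir / "spikeins.tsv", sep="\t", index=False)
        layout = {
            colname(rep, t): [rep, float(t)]
            for rep in truth.designs
            for t in truth.designs[rep]
        }
        cfg = {
            "t_d": truth.t_d,
            "doubling_time": float(LN2 / truth.alpha_growth),
            "rng_seed": int(seed),
            "layout": layout,
        }
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        pd.DataFrame(
            {
                "transcript_id": truth.transcript_ids,
                "alpha_rna": truth.alpha_rna,
                "alpha_total": truth.alpha_total,
                "half_life": truth.half_life,
                "y_eq_molecules": truth.y_eq,
                "nb_size": truth.dispersion,
            }
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    return ds
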