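"""Multi-spike-in normalization of labeled-count time series.

Constant-mass thiolated spike-ins are pulled down alongside labeled
transcripts, so a gene's count divided by a spike-in's count is free of
library-size and capture-efficiency variation.  The scheme, per replicate:

1. ratio A[i,n] = M[i] / S[n] for every gene i and spike-in n at each
   time point;
2. scaling factor beta[n] = mean over time points of S[n] / S[ref],
   which puts each spike-in's ratios on the reference spike-in's scale;
3. normalized ratio = A * beta;
4. rescale to count units by the mean reference-spike-in count across
   all time points of both replicates.

Rescaling every count in one library by a common factor (a pure depth
shift) cancels in every ratio, so it can only move the single global
count-scale constant of step 4 — every gene's time course keeps its exact
shape and every fitted rate is unchanged.

Because spike-ins enter at constant mass, their mutual ratios should be
time-invariant; a time point where any spike-in's ratio to the reference
strays more than ``deviance_threshold``-fold from that spike-in's median
ratio is excluded wholesale (all genes, that library).  A spike-in count of
zero marks the time point deviant outright — a vanished spike-in signals a
failed pull-down, not signal — and is never pseudocounted.

Each (replicate, time point, spike-in) normalized value is kept as a
separate observation for the fit, so a time point contributes as many
values as there are spike-ins per replicate measuring it;
``collapse_timepoints`` averages them instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, NormalizedSeries, RunConfig

__all__ = [
    "SpikeinDiagnostics",
    "compute_ratios",
    "compute_scaling_factors",
    "detect_deviant_timepoints",
    "normalize",
    "write_normalization_report",
]


@dataclass
class SpikeinDiagnostics:
    """Spike-in behavior per library, and the exclusion decisions.

    ``ratios`` columns: replicate, time_min, spikein, ratio_to_ref,
    median_ratio, fold_deviation, deviant.  ``timepoints`` columns:
    replicate, time_min, excluded, offending_spikeins.  ``beta`` columns:
    spikein, replicate, beta.
    """

    reference: str
    ratios: pd.DataFrame
    timepoints: pd.DataFrame
    beta: pd.DataFrame

    def excluded(self) -> list[tuple[str, float]]:
        bad = self.timepoints[self.timepoints["excluded"]]
        return list(zip(bad["replicate"], bad["time_min"]))


def _reference(cm: CountMatrix, reference: str | None) -> str:
    ref = reference if reference is not None else cm.spikein_ids[0]
    if ref not in cm.spikein_ids:
        raise ValueError(f"reference spike-in {ref!r} not among spike-ins {cm.spikein_ids}")
    return ref


def compute_ratios(cm: CountMatrix) -> pd.DataFrame:
    """Gene/spike-in count ratios A for every library.

    Returns a tidy frame (transcript, replicate, time_min, spikein, ratio).
    Where the spike-in count is zero the ratio is NaN; the library is dealt
    with by the deviance rule, never divided through a pseudocount.
    """
    genes = cm.gene_counts()
    spikes = cm.spike_counts()
    frames = []
    for spike_id in cm.spikein_ids:
        s = spikes.loc[spike_id]
        with np.errstate(divide="ignore", invalid="ignore"):
            a = genes.div(s.where(s > 0), axis=1)
        long = a.stack(["replicate", "time_min"], future_stack=True).rename("ratio").reset_index()
        long.columns = ["transcript", "replicate", "time_min", "ratio"]
        long["spikein"] = spike_id
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[["transcript", "replicate", "time_min", "spikein", "ratio"]]


def compute_scaling_factors(cm: CountMatrix, reference: str | None = None) -> pd.DataFrame:
    """Per-(spike-in, replicate) scaling factors beta.

    beta[n, j] = mean over time points k of S[n,j,k] / S[ref,j,k]; the
    reference's beta is exactly 1.  Time points where either count is zero
    are left out of the mean (they are excluded downstream anyway).
    """
    ref = _reference(cm, reference)
    spikes = cm.spike_counts()
    rows = []
    for rep in cm.replicates:
        s_ref = spikes.loc[ref, rep].to_numpy(float)
        for spike_id in cm.spikein_ids:
            if spike_id == ref:
                rows.append((spike_id, rep, 1.0))
                continue
            s_n = spikes.loc[spike_id, rep].to_numpy(float)
            ok = (s_ref > 0) & (s_n > 0)
            beta = float(np.mean(s_n[ok] / s_ref[ok])) if ok.any() else np.nan
            rows.append((spike_id, rep, beta))
    return pd.DataFrame(rows, columns=["spikein", "replicate", "beta"])


def detect_deviant_timepoints(cm: CountMatrix, cfg: RunConfig) -> SpikeinDiagnostics:
    """Flag libraries whose spike-ins misbehave.

    For each non-reference spike-in, the ratio to the reference should be
    constant over time; the fold deviation from its per-replicate median is
    compared with ``cfg.deviance_threshold``.  Zero counts (any spike-in)
    flag the library directly.
    """
    ref = _reference(cm, cfg.reference_spikein)
    spikes = cm.spike_counts()
    ratio_rows = []
    tp_rows = []
    for rep in cm.replicates:
        times = cm.timepoints(rep)
        s_ref = spikes.loc[ref, rep].to_numpy(float)
        offenders: dict[float, list[str]] = {t: [] for t in times}
        for spike_id in cm.spikein_ids:
            s_n = spikes.loc[spike_id, rep].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where((s_ref > 0) & (s_n > 0), s_n / s_ref, np.nan)
            finite = r[np.isfinite(r)]
            med = float(np.median(finite)) if finite.size else np.nan
            for t, rv, sn, sr in zip(times, r, s_n, s_ref):
                if sn == 0 or sr == 0:
                    fold, deviant = np.inf, True
                elif spike_id == ref:
                    fold, deviant = 1.0, False
                else:
                    fold = max(rv / med, med / rv) if med and np.isfinite(rv) else np.inf
                    deviant = bool(fold > cfg.deviance_threshold)
                if deviant:
                    offenders[t].append(spike_id)
                ratio_rows.append((rep, t, spike_id, rv, med, fold, deviant))
        for t in times:
            tp_rows.append((rep, t, bool(offenders[t]), ",".join(offenders[t])))
    ratios = pd.DataFrame(
        ratio_rows,
        columns=[
            "replicate", "time_min", "spikein",
            "ratio_to_ref", "median_ratio", "fold_deviation", "deviant",
        ],
    )
    timepoints = pd.DataFrame(
        tp_rows, columns=["replicate", "time_min", "excluded", "offending_spikeins"]
    )
    beta = compute_scaling_factors(cm, ref)
    return SpikeinDiagnostics(reference=ref, ratios=ratios, timepoints=timepoints, beta=beta)


def normalize(
    cm: CountMatrix, cfg: RunConfig
) -> tuple[list[NormalizedSeries], SpikeinDiagnostics]:
    """Spike-in-normalize every gene's time series.

    Returns one :class:`NormalizedSeries` per gene (spike-ins are not
    normalized against themselves) plus the spike-in diagnostics.  Excluded
    time points are retained in the output with ``included=False``.
    """
    diag = detect_deviant_timepoints(cm, cfg)
    ref = diag.reference
    spikes = cm.spike_counts()
    genes = cm.gene_counts()

    # mean reference count over all libraries restores the count scale
    scale = float(spikes.loc[ref].to_numpy(float).mean())

    beta = diag.beta.set_index(["spikein", "replicate"])["beta"]
    excluded = {(r, t) for r, t in diag.excluded()}

    blocks = []
    for rep in cm.replicates:
        times = np.array(cm.timepoints(rep), dtype=float)
        g = genes[rep].to_numpy(float)  # genes x times
        for spike_id in cm.spikein_ids:
            s = spikes.loc[spike_id, rep].to_numpy(float)
            b = beta.loc[(spike_id, rep)]
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(s > 0, g / s * b * scale, np.nan)
            inc = np.array([(rep, t) not in excluded for t in times]) & (s > 0)
            blocks.append((rep, times, spike_id, v, inc))

    series: list[NormalizedSeries] = []
    gene_ids = list(genes.index)
    for gi, gene in enumerate(gene_ids):
        recs = []
        for rep, times, spike_id, v, inc in blocks:
            for ti, t in enumerate(times):
                recs.append((rep, t, spike_id, v[gi, ti], bool(inc[ti])))
        pts = pd.DataFrame(
            recs, columns=["replicate", "time_min", "spikein", "value", "included"]
        )
        pts.loc[~np.isfinite(pts["value"]), "included"] = False
        if cfg.collapse_timepoints:
            inc = pts[pts["included"]]
            collapsed = (
                inc.groupby(["replicate", "time_min"], as_index=False)["value"].mean()
            )
            collapsed["spikein"] = "mean"
            collapsed["included"] = True
            drop = pts[~pts["included"]].drop_duplicates(["replicate", "time_min"])
            drop = drop[~drop.set_index(["replicate", "time_min"]).index.isin(
                collapsed.set_index(["replicate", "time_min"]).index)].copy()
            drop["spikein"] = "mean"
            pts = pd.concat([collapsed, drop], ignore_index=True)[
                ["replicate", "time_min", "spikein", "value", "included"]
            ]
        series.append(NormalizedSeries(transcript_id=gene, points=pts))
    return series, diag


def write_normalization_report(diag: SpikeinDiagnostics, path) -> None:
    """Write the per-library spike-in diagnostics as TSV."""
    rep = diag.ratios.merge(
        diag.timepoints, on=["replicate", "time_min"], how="left"
    ).merge(diag.beta, on=["spikein", "replicate"], how="left")
    rep.insert(0, "reference_spikein", diag.reference)
    rep.to_csv(path, sep="\t", index=False, float_format="%.6g")
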