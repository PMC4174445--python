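"""Core containers and tabular I/O.

Everything the pipeline reads or writes is plain TSV/YAML: a counts table
(rows = transcripts and spike-ins, columns = libraries), a spike-in manifest
(id, length_nt), a run config, and the estimates/report outputs.  Transcript
identifiers are opaque strings; no genome annotation is parsed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinetics import alpha_growth_from_doubling

__all__ = [
    "CountMatrix",
    "RunConfig",
    "NormalizedSeries",
    "KineticEstimate",
    "read_counts",
    "read_layout",
    "read_config",
    "write_counts",
    "write_estimates",
    "read_estimates",
    "read_abundances",
    "read_go_map",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountMatrix:
    """Per-transcript, per-library raw read counts.

    ``counts`` is indexed by transcript id with a two-level column index
    ``(replicate, time_min)``; time points are strictly increasing within a
    replicate.  ``spikein_ids`` marks the rows that are exogenous
    constant-mass spike-ins (at least one is required — they anchor the
    normalization).
    """

    counts: pd.DataFrame
    spikein_ids: list[str]
    spikein_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- views -----------------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        spikes = set(self.spikein_ids)
        return [t for t in self.counts.index if t not in spikes]

    @property
    def replicates(self) -> list[str]:
        seen: dict[str, None] = {}
        for rep, _ in self.counts.columns:
            seen.setdefault(rep, None)
        return list(seen)

    def timepoints(self, replicate: str) -> list[float]:
        return [t for rep, t in self.counts.columns if rep == replicate]

    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.spikein_ids]

    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.gene_ids]

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate transcript ids: {list(dups)[:5]}")
        if not self.spikein_ids:
            raise ValidationError("at least one spike-in is required")
        missing = [s for s in self.spikein_ids if s not in self.counts.index]
        if missing:
            raise ValidationError(f"spike-ins absent from count table: {missing}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            bad = self.counts.index[(~np.isfinite(vals) | (vals < 0)).any(axis=1)]
            raise ValidationError(f"negative or non-finite counts in rows: {list(bad)[:5]}")
        for rep in self.replicates:
            times = self.timepoints(rep)
            if any(t <= 0 for t in times):
                raise ValidationError(f"non-positive time point in replicate {rep!r}")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError(
                    f"time points not strictly increasing in replicate {rep!r}: {times}"
                )


@dataclass
class RunConfig:
    """Analysis parameters shared across the pipeline.

    ``t_d`` is the detection delay (min) fixed in the fit; ``doubling_time``
    (min) sets the dilution rate ln(2)/doubling_time subtracted from the
    fitted total rate.  ``deviance_threshold`` is the fold-change on
    spike-in/reference ratios beyond which a time point is discarded.
    ``weight_floor`` bounds the 1/Y regression weights away from infinity at
    zero counts.
    """

    t_d: float = 2.0
    doubling_time: float = 100.0
    n_bootstrap: int = 1000
    rng_seed: int = 0
    reference_spikein: str | None = None
    deviance_threshold: float = 2.0
    weight_floor: float = 0.5
    min_points: int = 3
    min_distinct_times: int = 2
    min_bootstrap_converged_frac: float = 0.5
    collapse_timepoints: bool = False
    bootstrap_unit: str = "observation"  # or "timepoint"
    synthesis_mode: str = "total"  # or "rna_only"
    total_mrna_per_cell: float = 60000.0
    enrichment_min_size: int = 5
    alpha_max: float = 10.0

    def __post_init__(self) -> None:
        if self.t_d < 0:
            raise ValueError("t_d must be >= 0")
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be > 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.deviance_threshold <= 0 or self.weight_floor <= 0:
            raise ValueError("deviance_threshold and weight_floor must be > 0")
        if self.bootstrap_unit not in ("observation", "timepoint"):
            raise ValueError("bootstrap_unit must be 'observation' or 'timepoint'")
        if self.synthesis_mode not in ("total", "rna_only"):
            raise ValueError("synthesis_mode must be 'total' or 'rna_only'")

    @property
    def alpha_growth(self) -> float:
        return alpha_growth_from_doubling(self.doubling_time)


@dataclass
class NormalizedSeries:
    """Spike-in-normalized labeled counts for one transcript.

    ``points`` columns: replicate, time_min, spikein, value, included.
    Each (replicate, time point, spike-in) normalized value is a separate
    observation; points at excluded time points carry ``included=False`` and
    never enter a fit.
    """

    transcript_id: str
    points: pd.DataFrame

    def included(self) -> pd.DataFrame:
        return self.points[self.points["included"]]

    @property
    def fittable(self) -> bool:
        inc = self.included()
        return len(inc) > 0 and (inc["value"] > 0).any()


@dataclass
class KineticEstimate:
    """Fitted decay parameters for one transcript.

    ``alpha_total`` is the observed labeling rate (degradation + dilution);
    ``alpha_rna`` subtracts the growth constant.  ``half_life`` is
    ln(2)/alpha_rna, NaN when undefined.  CI bounds are percentile-bootstrap
    bounds on alpha_total.
    """

    transcript_id: str
    alpha_total: float = float("nan")
    alpha_rna: float = float("nan")
    y_eq: float = float("nan")
    half_life: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_points_used: int = 0
    converged: bool = False
    n_bootstrap_failures: int = 0
    ci_unreliable: bool = False


# ---------------------------------------------------------------------------
# readers


def read_layout(source) -> dict[str, tuple[str, float]]:
    """Load a column-layout map ``{column: (replicate, time_min)}``.

    Accepts a dict already in that shape or a path to a YAML file with a
    top-level ``layout`` key (or the mapping itself).
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw, Mapping) and "layout" in raw:
            raw = raw["layout"]
    layout: dict[str, tuple[str, float]] = {}
    for col, spec in raw.items():
        rep, t = spec
        layout[str(col)] = (str(rep), float(t))
    return layout


def read_config(path) -> tuple[RunConfig, dict[str, tuple[str, float]] | None]:
    """Read a YAML run config; returns (RunConfig, layout-or-None)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    layout = read_layout(raw["layout"]) if "layout" in raw else None
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in fields})
    return cfg, layout


def _read_manifest(path) -> dict[str, int]:
    man = pd.read_csv(path, sep="\t", dtype={0: str})
    if "id" not in man.columns:
        raise ValidationError(f"spike-in manifest {path} needs an 'id' column")
    lengths = {}
    for _, row in man.iterrows():
        lengths[str(row["id"])] = int(row["length_nt"]) if "length_nt" in man.columns else 0
    if not lengths:
        raise ValidationError(f"spike-in manifest {path} is empty")
    return lengths


def read_counts(path, spikein_manifest, layout) -> CountMatrix:
    """Read a TSV count table into a validated :class:`CountMatrix`.

    ``layout`` maps column names to (replicate, time_min); columns not in the
    layout (other than the id column) raise.  Spike-in ids named in the
    manifest must be present in the table.
    """
    layout = read_layout(layout)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index = df.index.astype(str)

    missing = [c for c in layout if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: layout names missing columns {missing}")
    extra = [c for c in df.columns if c not in layout]
    if extra:
        raise ValidationError(f"{path}: columns not described by layout: {extra}")

    cols = sorted(layout, key=lambda c: layout[c])
    mat = df[cols]
    try:
        mat = mat.astype(float)
    except ValueError as exc:  # pragma: no cover - pandas message is informative
        raise ValidationError(f"{path}: non-numeric counts ({exc})") from exc
    mat.columns = pd.MultiIndex.from_tuples(
        [layout[c] for c in cols], names=["replicate", "time_min"]
    )

    lengths = _read_manifest(spikein_manifest)
    unknown = [s for s in lengths if s not in mat.index]
    if unknown:
        raise ValidationError(f"manifest spike-ins absent from {path}: {unknown}")
    return CountMatrix(counts=mat, spikein_ids=list(lengths), spikein_lengths=lengths)


def read_abundances(path) -> pd.Series:
    """Read a transcript-abundance TSV (id, mrnas_per_cell) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0], name="mrnas_per_cell")


def read_go_map(path) -> pd.DataFrame:
    """Read a gene→term membership TSV (gene_id, term_id[, term_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "term_id"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: GO map needs columns {sorted(need)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df


# ---------------------------------------------------------------------------
# writers

_EST_COLUMNS = [
    "transcript_id",
    "alpha_total",
    "alpha_rna",
    "half_life",
    "ci_low",
    "ci_high",
    "y_eq",
    "k_synthesis",
    "k_ci_low",
    "k_ci_high",
    "converged",
]


def write_counts(cm: CountMatrix, path, column_name=lambda rep, t: f"{rep}_t{t:g}") -> None:
    """Write a CountMatrix back to TSV with flat library column names."""
    out = cm.counts.copy()
    out.columns = [column_name(rep, t) for rep, t in out.columns]
    out.index.name = "transcript_id"
    out.astype(int).to_csv(path, sep="\t")


def write_estimates(estimates: Sequence[KineticEstimate], path, synthesis=None) -> None:
    """Write one TSV row per transcript; non-converged rows carry NA fields.

    ``synthesis`` is an optional mapping transcript_id -> SynthesisEstimate
    whose k / CI columns are merged in.
    """
    if not estimates:
        raise ValueError("no estimates to write")
    syn = synthesis or {}
    rows = []
    for e in estimates:
        s = syn.get(e.transcript_id)
        if e.converged:
            row = dict(
                transcript_id=e.transcript_id,
                alpha_total=e.alpha_total,
                alpha_rna=e.alpha_rna,
                half_life=e.half_life,
                ci_low=e.ci_low,
                ci_high=e.ci_high,
                y_eq=e.y_eq,
            )
        else:
            row = dict(transcript_id=e.transcript_id)
        row["k_synthesis"] = getattr(s, "k", float("nan"))
        row["k_ci_low"] = getattr(s, "k_ci_low", float("nan"))
        row["k_ci_high"] = getattr(s, "k_ci_high", float("nan"))
        row["converged"] = e.converged
        rows.append(row)
    df = pd.DataFrame(rows, columns=_EST_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_estimates(path) -> pd.DataFrame:
    """Read an estimates TSV written by :func:`write_estimates`."""
    return pd.read_csv(path, sep="\t", na_values="NA")
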