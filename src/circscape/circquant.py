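"""Back-splice-junction (BSJ) quantification statistics.

A circRNA is detected through reads that span its back-splice junction —
the non-colinear junction joining a downstream splice donor to an upstream
splice acceptor. This module holds the bookkeeping for BSJ candidates
(caller harmonization, abundance filtering) and the per-candidate
expression statistics used to describe a circRNA landscape:

* RPM — BSJ-spanning reads per million total library reads;
* CTL ratio — circular-to-linear ratio, BSJ reads over the mean of the
  linear reads at the same donor and acceptor sites plus a pseudocount;
* median-of-ratios size-factor normalization;
* log2 + pseudocount z-scaling for marker heatmaps.

Coordinates are 0-based half-open (BED convention): ``start`` is the
acceptor position, ``end`` the exclusive donor position on the annotated
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircCandidate",
    "JunctionCountSet",
    "ExpressionSummary",
    "NormalizationResult",
    "harmonize_callers",
    "filter_high_abundance",
    "rpm",
    "ctl_ratio",
    "median_of_ratios",
    "log2_z_matrix",
    "percent_of_total",
    "total_reads_for_mean",
]


class FormatError(ValueError):
    """Malformed coordinates or inconsistent table shapes."""


class NormalizationError(ValueError):
    """No row usable as a median-of-ratios reference."""


@dataclass(frozen=True)
class CircCandidate:
    """One BSJ locus.

    ``start`` (acceptor) < ``end`` (exclusive donor), 0-based half-open.
    ``callers`` records which detection pipelines reported the locus;
    ``inspection`` is ``"pass"``, ``"fail"`` or ``"unreviewed"`` and models
    the manual review of single-caller candidates.
    """

    chrom: str
    start: int
    end: int
    strand: str
    annotation_id: str | None = None
    callers: frozenset[str] = frozenset()
    inspection: str = "unreviewed"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.inspection not in ("pass", "fail", "unreviewed"):
            raise ValueError(f"bad inspection state {self.inspection!r}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def locus(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class JunctionCountSet:
    """BSJ and linear junction counts for candidates x samples.

    ``samples`` is a DataFrame indexed by sample id with columns
    ``condition``, ``replicate`` and ``library_size`` (total reads).
    ``bsj``, ``donor_linear`` and ``acceptor_linear`` are DataFrames with
    candidate ids as index and sample ids as columns.
    """

    candidates: list[CircCandidate]
    samples: pd.DataFrame
    bsj: pd.DataFrame
    donor_linear: pd.DataFrame
    acceptor_linear: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [c.id for c in self.candidates]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate candidate ids")
        sample_ids = list(self.samples.index)
        for name in ("bsj", "donor_linear", "acceptor_linear"):
            mat = getattr(self, name)
            if list(mat.index) != ids or list(mat.columns) != sample_ids:
                raise FormatError(f"{name} matrix not aligned to candidates/samples")
            if (mat.to_numpy() < 0).any():
                raise FormatError(f"negative counts in {name}")
        if (self.samples["library_size"] <= 0).any():
            raise ValueError("library_size must be positive for every sample")

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, keep_ids: Sequence[str]) -> "JunctionCountSet":
        keep = list(keep_ids)
        by_id = {c.id: c for c in self.candidates}
        return JunctionCountSet(
            candidates=[by_id[i] for i in keep],
            samples=self.samples,
            bsj=self.bsj.loc[keep],
            donor_linear=self.donor_linear.loc[keep],
            acceptor_linear=self.acceptor_linear.loc[keep],
        )


@dataclass
class ExpressionSummary:
    """Per-candidate, per-sample RPM and CTL ratio with condition means."""

    rpm: pd.DataFrame
    ctl: pd.DataFrame
    mean_rpm: pd.DataFrame          # candidates x conditions
    mean_ctl: pd.DataFrame
    pseudocount_ctl: float = 1.0


@dataclass
class NormalizationResult:
    size_factors: pd.Series
    normalized_counts: pd.DataFrame


def harmonize_callers(
    calls_a: Iterable[CircCandidate],
    calls_b: Iterable[CircCandidate],
    caller_a: str = "find_circ",
    caller_b: str = "CIRCexplorer",
    exclusion: Iterable[tuple[str, int, int, str]] | None = None,
    drop_failed: bool = False,
) -> list[CircCandidate]:
    """Merge two callers' candidate lists on identical loci.

    Candidates reported by both callers get ``callers={caller_a, caller_b}``
    and ``inspection='pass'``. Single-caller candidates stay ``unreviewed``
    (they would need manual inspection for mapping artifacts). ``exclusion``
    is an explicit locus list standing in for that manual review: matching
    candidates are marked ``inspection='fail'`` and dropped when
    ``drop_failed`` is set.
    """
    a_by_locus = {c.locus: c for c in calls_a}
    b_loci = {c.locus for c in calls_b}
    excl = set(exclusion or ())

    merged: list[CircCandidate] = []
    for locus, cand in a_by_locus.items():
        shared = locus in b_loci
        callers = frozenset({caller_a, caller_b} if shared else {caller_a})
        inspection = "pass" if shared else "unreviewed"
        if locus in excl:
            inspection = "fail"
        merged.append(replace(cand, callers=callers, inspection=inspection))
    for cand in calls_b:
        if cand.locus not in a_by_locus:
            inspection = "fail" if cand.locus in excl else "unreviewed"
            merged.append(
                replace(cand, callers=frozenset({caller_b}), inspection=inspection)
            )
    if drop_failed:
        merged = [c for c in merged if c.inspection != "fail"]
    return merged


def filter_high_abundance(
    jcs: JunctionCountSet, min_mean: float = 5.0
) -> JunctionCountSet:
    """Keep candidates averaging at least ``min_mean`` BSJ reads per sample.

    Inclusive at the boundary: a candidate with a mean of exactly
    ``min_mean`` is retained. Candidate order is preserved.
    """
    if jcs.n_samples < 1:
        raise ValueError("need at least one sample")
    means = jcs.bsj.mean(axis=1)
    keep = [c.id for c in jcs.candidates if means[c.id] >= min_mean]
    return jcs.subset(keep)


def rpm(jcs: JunctionCountSet) -> pd.DataFrame:
    """Reads per million: BSJ count / library size x 1e6, per sample."""
    lib = jcs.samples["library_size"].astype(float)
    if (lib <= 0).any():
        raise ValueError("library_size must be positive")
    return jcs.bsj.astype(float).div(lib, axis=1) * 1e6


def ctl_ratio(jcs: JunctionCountSet, pseudocount: float = 1.0) -> pd.DataFrame:
    """Circular-to-linear ratio per candidate and sample.

    ctl = bsj / ((donor + acceptor)/2 + pseudocount); the pseudocount keeps
    the denominator positive when no linear reads span either site.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for mat in (jcs.bsj, jcs.donor_linear, jcs.acceptor_linear):
        if (mat.to_numpy() < 0).any():
            raise ValueError("negative counts")
    denom = (jcs.donor_linear + jcs.acceptor_linear) / 2.0 + pseudocount
    return jcs.bsj / denom


def summarize_expression(
    jcs: JunctionCountSet, pseudocount_ctl: float = 1.0
) -> ExpressionSummary:
    """Compute RPM and CTL matrices plus per-condition means."""
    rpm_mat = rpm(jcs)
    ctl_mat = ctl_ratio(jcs, pseudocount=pseudocount_ctl)
    cond = jcs.samples["condition"]
    order = list(dict.fromkeys(cond))  # condition order of appearance
    mean_rpm = rpm_mat.T.groupby(cond).mean().T[order]
    mean_ctl = ctl_mat.T.groupby(cond).mean().T[order]
    return ExpressionSummary(
        rpm=rpm_mat,
        ctl=ctl_mat,
        mean_rpm=mean_rpm,
        mean_ctl=mean_ctl,
        pseudocount_ctl=pseudocount_ctl,
    )


def median_of_ratios(counts: pd.DataFrame | np.ndarray) -> NormalizationResult:
    """Median-of-ratios size factors (rows = features, columns = samples).

    The pseudo-reference is the row-wise geometric mean over rows with all
    counts > 0; each sample's size factor is the median ratio of its counts
    to the reference over those rows. Normalized counts divide each column
    by its size factor.
    """
    df = pd.DataFrame(counts).astype(float)
    mat = df.to_numpy()
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError("no row with all-positive counts")
    pos = mat[all_pos]
    log_ref = np.mean(np.log(pos), axis=1)
    factors = np.median(np.exp(np.log(pos) - log_ref[:, None]), axis=0)
    size_factors = pd.Series(factors, index=df.columns, name="size_factor")
    return NormalizationResult(
        size_factors=size_factors,
        normalized_counts=df.div(size_factors, axis=1),
    )


def log2_z_matrix(
    counts: pd.DataFrame | np.ndarray, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Row-wise z-scores of log2(count + pseudocount), sample sd (ddof=1).

    Constant rows (sd = 0) map to all-zero z-scores; this is a display
    convention for marker heatmaps, not a statistic.
    """
    df = pd.DataFrame(counts).astype(float)
    logged = np.log2(df + pseudocount)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    sd = sd.where(sd > 1e-12, np.nan)  # constant rows (up to roundoff) -> 0
    z = logged.sub(mu, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


def percent_of_total(count: float, total: float, ndigits: int = 1) -> float:
    """Share of ``total`` as a percentage rounded to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def total_reads_for_mean(mean_per_sample: float, n_samples: int) -> float:
    """Total read count equivalent to a per-sample mean across n samples."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return mean_per_sample * n_samples
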