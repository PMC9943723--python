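"""CNV call QC, probe-by-sample matrix construction and probe selection.

The scan operates on a probe-by-sample copy-number state matrix (deletion
= −1, copy-neutral = 0, duplication = +1, NaN = missing) built from
PennCNV-style CNV calls restricted to a focal region.  Calls pass a
quality-score filter and batch-level outlier exclusions first; probes are
then filtered on genotype missingness and pruned to a highly inter-correlated
proxy set that still tags every CNV in the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised low-copy-repeat flanked CNV categories plus the catch-all.
LCR_CATEGORIES = ("A-B", "A-D", "B-D", "C-D", "atypical")

#: Recognised (start LCR, end LCR) anchor pairs.
_LCR_PAIRS = (("A", "B"), ("A", "D"), ("B", "D"), ("C", "D"))

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_class", "qs"]


@dataclass
class CnvMatrix:
    """Probe-by-sample copy-number state matrix.

    ``states`` is a float array of shape (n_probes, n_samples) with entries
    in {−1, 0, +1} and NaN for missing; probes are ordered by position.
    """

    probe_ids: list = field(default_factory=list)
    probe_bp: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sample_ids: list = field(default_factory=list)
    states: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self):
        self.probe_bp = np.asarray(self.probe_bp, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.probe_bp) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if self.states.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("states shape does not match probe/sample labels")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probe_id) -> np.ndarray:
        return self.states[self.probe_ids.index(probe_id)]

    def subset_probes(self, probe_ids) -> "CnvMatrix":
        idx = [self.probe_ids.index(p) for p in probe_ids]
        idx.sort(key=lambda i: self.probe_bp[i])
        return CnvMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            probe_bp=self.probe_bp[idx],
            sample_ids=list(self.sample_ids),
            states=self.states[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, index=self.probe_ids, columns=self.sample_ids)
        df.insert(0, "bp", self.probe_bp)
        df.index.name = "probe_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CnvMatrix":
        bp = df["bp"].to_numpy(dtype=np.int64)
        states = df.drop(columns=["bp"]).to_numpy(dtype=float)
        return cls(
            probe_ids=list(df.index),
            probe_bp=bp,
            sample_ids=list(df.columns[1:]),
            states=states,
        )


# ---------------------------------------------------------------------------
# Call-level quality control


def qc_filter_calls(
    calls: pd.DataFrame,
    per_sample_counts=None,
    per_plate_means=None,
    sample_plate=None,
    qs_min: float = 0.5,
    max_sample_calls: int = 200,
    max_plate_mean: float = 100.0,
    max_call_length: int = 10_000_000,
):
    """Apply quality-score and batch-outlier filters to CNV calls.

    Exclusion rules: (a) samples on genotyping plates whose mean CNV count
    per sample exceeds ``max_plate_mean``; (b) samples with more than
    ``max_sample_calls`` calls genome-wide; (c) samples harbouring any single
    call longer than ``max_call_length``; then (d) remaining calls with
    |QS| < ``qs_min`` are dropped.  Counts (a)–(b) refer to genome-wide
    totals and may be supplied via ``per_sample_counts`` (mapping sample →
    count) and ``per_plate_means`` (mapping plate → mean count) together with
    ``sample_plate`` (mapping sample → plate); when omitted they are derived
    from the provided call table itself.

    Returns ``(retained_calls, excluded_sample_ids)``.
    """
    calls = calls.reset_index(drop=True)
    if not calls.shape[0]:
        return calls, []

    samples = calls["sample_id"]
    if per_sample_counts is None:
        per_sample_counts = samples.value_counts().to_dict()
    else:
        per_sample_counts = dict(per_sample_counts)
        unknown = set(samples) - set(per_sample_counts)
        if unknown:
            raise ValueError(f"calls reference samples without counts: {sorted(unknown)[:5]}")

    excluded = set()
    if per_plate_means is not None and sample_plate is not None:
        bad_plates = {p for p, m in dict(per_plate_means).items() if m > max_plate_mean}
        excluded |= {s for s, p in dict(sample_plate).items() if p in bad_plates}
    excluded |= {s for s, c in per_sample_counts.items() if c > max_sample_calls}

    lengths = calls["end"] - calls["start"] + 1
    excluded |= set(samples[lengths > max_call_length])

    keep = ~samples.isin(excluded) & (calls["qs"].abs() >= qs_min)
    return calls[keep].reset_index(drop=True), sorted(excluded)


# ---------------------------------------------------------------------------
# Matrix construction


def build_matrix(calls: pd.DataFrame, probes: pd.DataFrame, sample_ids=None) -> CnvMatrix:
    """Transform QC-passed calls into a probe-by-sample state matrix.

    ``probes`` needs columns ``probe_id`` and ``bp`` (position-sorted or
    not — they are sorted here).  A probe is covered by a call iff
    ``start <= bp <= end`` (1-based inclusive).  Samples listed in
    ``sample_ids`` but carrying no call get all-zero columns.  If a sample
    has both a deletion and a duplication covering the same probe the entry
    is set missing (NaN) — the state is ambiguous.
    """
    probes = probes.sort_values("bp").reset_index(drop=True)
    bp = probes["bp"].to_numpy(dtype=np.int64)
    if sample_ids is None:
        sample_ids = sorted(pd.unique(calls["sample_id"]))
    else:
        sample_ids = list(sample_ids)
    sample_index = {s: j for j, s in enumerate(sample_ids)}

    n_p, n_s = len(bp), len(sample_ids)
    has_del = np.zeros((n_p, n_s), dtype=bool)
    has_dup = np.zeros((n_p, n_s), dtype=bool)
    for rec in calls.itertuples(index=False):
        try:
            j = sample_index[rec.sample_id]
        except KeyError:
            raise ValueError(f"call references unknown sample {rec.sample_id!r}") from None
        lo = np.searchsorted(bp, rec.start, side="left")
        hi = np.searchsorted(bp, rec.end, side="right")
        if rec.cn_class == "del":
            has_del[lo:hi, j] = True
        elif rec.cn_class == "dup":
            has_dup[lo:hi, j] = True
        else:
            raise ValueError(f"unknown cn_class {rec.cn_class!r} (expected 'del'/'dup')")

    states = np.zeros((n_p, n_s))
    states[has_del] = -1.0
    states[has_dup] = 1.0
    states[has_del & has_dup] = np.nan
    return CnvMatrix(
        probe_ids=list(probes["probe_id"]),
        probe_bp=bp,
        sample_ids=sample_ids,
        states=states,
    )


def classify_call(call, lcr_positions: dict, tolerance: int = 20_000) -> str:
    """Assign a call to an LCR category (A-B, A-D, B-D, C-D or atypical).

    ``lcr_positions`` maps LCR name (A–D) to its (start, end) interval.  A
    call is X-Y anchored iff its start lies within ``tolerance`` bp of LCR X
    (interval edges included) and its end within ``tolerance`` of LCR Y, for
    one of the recognised pairs; anything else is atypical.
    """
    for name in "ABCD":
        if name not in lcr_positions:
            raise ValueError(f"missing LCR coordinates for {name!r}")

    start = call["start"] if isinstance(call, (dict, pd.Series)) else call.start
    end = call["end"] if isinstance(call, (dict, pd.Series)) else call.end

    def near(pos, lcr):
        lo, hi = lcr_positions[lcr]
        return lo - tolerance <= pos <= hi + tolerance

    for x, y in _LCR_PAIRS:
        if near(start, x) and near(end, y):
            return f"{x}-{y}"
    return "atypical"


# ---------------------------------------------------------------------------
# Probe summaries and selection


def probe_frequencies(matrix: CnvMatrix) -> pd.DataFrame:
    """Per-probe duplication and deletion carrier frequencies.

    The denominator is the number of samples with a non-missing state at the
    probe; a probe with all entries missing gets NaN frequencies.
    """
    s = matrix.states
    n_ok = np.sum(~np.isnan(s), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_dup = np.where(n_ok > 0, np.nansum(s == 1, axis=1) / n_ok, np.nan)
        freq_del = np.where(n_ok > 0, np.nansum(s == -1, axis=1) / n_ok, np.nan)
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "bp": matrix.probe_bp,
            "freq_dup": freq_dup,
            "freq_del": freq_del,
            "missingness": 1.0 - n_ok / max(matrix.n_samples, 1),
        }
    )


def filter_missingness(matrix: CnvMatrix, max_missing: float = 0.05) -> list:
    """Probe ids whose missing fraction does not exceed ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    miss = np.mean(np.isnan(matrix.states), axis=1)
    return [p for p, m in zip(matrix.probe_ids, miss) if m <= max_missing]


def probe_correlation(matrix: CnvMatrix) -> np.ndarray:
    """Pairwise Pearson correlation of raw CN states across probes.

    Pairwise-complete observations; zero-variance probes get correlation 0
    with every other probe (they can never act as pruning partners).
    """
    s = matrix.states
    if not np.isnan(s).any():
        sd = s.std(axis=1)
        ok = sd > 0
        r = np.zeros((s.shape[0], s.shape[0]))
        if ok.any():
            r_ok = np.corrcoef(s[ok])
            r[np.ix_(ok, ok)] = np.atleast_2d(r_ok)
        np.fill_diagonal(r, 1.0)
        return r
    # NaN-aware fallback: pandas pairwise-complete correlation
    r = pd.DataFrame(s.T).corr(min_periods=2).to_numpy()
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def prune_probes(
    matrix: CnvMatrix,
    r2_min: float = 0.999,
    min_partners: int = 10,
    corr: np.ndarray | None = None,
) -> list:
    """Retain probes highly correlated (r² ≥ ``r2_min``) with at least
    ``min_partners`` other probes.

    This keeps dense proxy probes tagging recurrent CNVs while dropping
    probes with idiosyncratic state patterns, shrinking the multiple-testing
    burden without losing the CNV landscape.
    """
    if corr is None:
        corr = probe_correlation(matrix)
    r2 = corr**2
    np.fill_diagonal(r2, 0.0)
    n_partners = np.sum(r2 >= r2_min, axis=1)
    return [p for p, k in zip(matrix.probe_ids, n_partners) if k >= min_partners]


def probe_summary(
    matrix: CnvMatrix,
    max_missing: float = 0.05,
    r2_min: float = 0.999,
    min_partners: int = 10,
    exclude_mask=None,
) -> pd.DataFrame:
    """Frequencies + missingness + retention flags, one row per probe.

    ``exclude_mask`` optionally marks probes (e.g. those inside LCRA) to be
    flagged out of frequency summaries.
    """
    out = probe_frequencies(matrix)
    keep_miss = set(filter_missingness(matrix, max_missing))
    sub = matrix.subset_probes(sorted(keep_miss, key=matrix.probe_ids.index))
    keep_prune = set(prune_probes(sub, r2_min, min_partners))
    out["pass_missingness"] = out["probe_id"].isin(keep_miss)
    out["retained"] = out["probe_id"].isin(keep_prune)
    if exclude_mask is not None:
        out["excluded_from_summary"] = np.asarray(exclude_mask, dtype=bool)
    return out
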