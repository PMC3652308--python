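"""Adapter trimming, isomiR-tolerant alignment and miRNA counting.

The quantification path mirrors a SOLiD-era small-RNA protocol operating in
base space: 50-base reads carry a 15-base tag end that is removed first,
then 5'/3' adapter segments are located by alignment scoring and excised,
the 5' terminal nucleotide is dropped, and reads longer than 15 bases are
aligned to the mature-miRNA reference.  Alignment tolerates isomiRs: up to
2 extra and 2 missing bases at either end and up to 3 substitutions, with
the best-scoring assignment winning.  Counts are produced per precursor
and merged per mature sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import (
    DEFAULT_ADAPTER_3P,
    DEFAULT_ADAPTER_5P,
    MiRNAReference,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrimParams",
    "MatchParams",
    "CountMatrix",
    "TrimResult",
    "trim_reads",
    "align_and_count",
    "align_filter_db",
    "merge_counts",
    "cpm_filter",
]


@dataclass
class TrimParams:
    """Trimming parameters; defaults follow the 50-base protocol."""

    end_trim: int = 15
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -2
    min_adapter_overlap: int = 6
    min_3p_overlap: int = 3
    drop_5p_terminal: bool = True
    min_length: int = 16  # keep reads of length > 15

    def __post_init__(self) -> None:
        if self.end_trim < 0:
            raise ValueError("end_trim must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class MatchParams:
    """IsomiR tolerance for read-to-mature matching.

    ``five_prime_clip`` exempts that many missing 5' reference bases from
    the isomiR budget: the trimming protocol deterministically removes the
    5' terminal nucleotide of every read, and that known clip should not
    consume the +-2 isomiR allowance.
    """

    max_mismatches: int = 3
    iso_extend: int = 2
    iso_trim: int = 2
    five_prime_clip: int = 1

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.max_mismatches > 3:
            raise ValueError("max_mismatches must be in [0, 3]")
        if not (0 <= self.iso_extend <= 2 and 0 <= self.iso_trim <= 2):
            raise ValueError("iso_extend/iso_trim must be in [0, 2]")
        if self.five_prime_clip < 0:
            raise ValueError("five_prime_clip must be >= 0")


@dataclass
class CountMatrix:
    """Integer feature x library read counts with annotations.

    Library sizes are defined as the per-library column sums; normalization
    factors default to 1 and multiply the library size to give effective
    sizes for CPM and testing.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame  # index = feature; precursor_id, mature_id, star_flag
    norm_factors: pd.Series | None = None
    min_count_threshold: int = 1

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        if (self.norm_factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        missing = set(self.counts.index) - set(self.annotations.index)
        if missing:
            raise ValueError(f"features without annotations: {sorted(missing)[:5]}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        eff = self.library_sizes * self.norm_factors
        return self.counts / eff * 1e6


def _overlap_score(a: str, b: str, match: int, mismatch: int) -> int:
    """Ungapped score of two equal-length strings."""
    s = 0
    for x, y in zip(a, b):
        s += match if x == y else mismatch
    return s


def _locate_5p(core: str, adapter: str, params: TrimParams) -> int:
    """Length of the 5' adapter fragment at the read start (0 if none).

    The fragment is a suffix of the adapter aligned to the read prefix
    (overlap alignment, ungapped): the best-scoring overlap with score >=
    min_adapter_overlap wins; exact full-adapter occurrence is recognised
    first as a fast path.
    """
    la = len(adapter)
    if la and core.startswith(adapter):
        return la
    best_k, best_score = 0, params.min_adapter_overlap - 1
    for k in range(min(la, len(core)), 0, -1):
        if core[:k] == adapter[-k:]:
            score = k * params.sw_match
        else:
            score = _overlap_score(core[:k], adapter[-k:], params.sw_match, params.sw_mismatch)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def _locate_3p(core: str, adapter: str, params: TrimParams) -> int:
    """Length of the 3' adapter fragment at the read end (0 if none).

    The fragment is a prefix of the adapter running off the read's 3' end.
    The longest exact prefix match of length >= min_3p_overlap is
    preferred; otherwise the best-scoring ungapped overlap with score >=
    min_adapter_overlap (mismatch-containing fragments need the stronger
    evidence).
    """
    la = len(adapter)
    for k in range(min(la, len(core)), params.min_3p_overlap - 1, -1):
        if core.endswith(adapter[:k]):
            return k
    best_k, best_score = 0, params.min_adapter_overlap - 1
    for k in range(min(la, len(core)), 0, -1):
        score = _overlap_score(core[-k:], adapter[:k], params.sw_match, params.sw_mismatch)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


@dataclass
class TrimResult:
    reads: list[tuple[str, str]]
    n_input: int = 0
    n_rejected: int = 0  # non-ACGTN characters
    n_adapter: int = 0  # reads in which an adapter/primer segment was found
    n_short: int = 0  # discarded below min_length
    audit: list[str] = field(default_factory=list)


_VALID = set("ACGTN")


def trim_reads(reads, params: TrimParams | None = None, keep_audit: bool = False) -> TrimResult:
    """Trim tag ends and adapters; drop the 5' base and short reads.

    ``reads`` is an iterable of (read_id, sequence) in base space.  Pipeline
    order: (1) remove the last ``end_trim`` bases; (2) excise 5'/3'
    adapter segments located by overlap-alignment scoring; (3) drop the
    first remaining base if ``drop_5p_terminal``; (4) discard reads shorter
    than ``min_length``.
    """
    params = params or TrimParams()
    out = TrimResult(reads=[])
    for rid, seq in reads:
        out.n_input += 1
        if set(seq) - _VALID:
            out.n_rejected += 1
            if keep_audit:
                out.audit.append(f"{rid}\treject\tnon-ACGTN")
            continue
        core = seq[: len(seq) - params.end_trim] if params.end_trim else seq
        l5 = _locate_5p(core, params.adapter_5p, params) if params.adapter_5p else 0
        if l5:
            core = core[l5:]
        l3 = _locate_3p(core, params.adapter_3p, params) if params.adapter_3p else 0
        if l3:
            core = core[: len(core) - l3]
        if l5 or l3:
            out.n_adapter += 1
        if params.drop_5p_terminal and core:
            core = core[1:]
        if len(core) < params.min_length:
            out.n_short += 1
            if keep_audit:
                out.audit.append(f"{rid}\tshort\tlen={len(core)}")
            continue
        if keep_audit:
            out.audit.append(f"{rid}\tkeep\t5p={l5}\t3p={l3}\tlen={len(core)}")
        out.reads.append((rid, core))
    return out


class _Matcher:
    """IsomiR-tolerant matcher against a set of reference sequences.

    A read matches a reference if, for some end offset, the overlapping
    region has <= max_mismatches substitutions, read overhangs beyond
    either reference end are <= iso_extend bases, and uncovered reference
    bases at either end are <= iso_trim.  Candidates are generated through
    a 5-mer index (pigeonhole over <= 3 substitutions) plus an exact
    truncation dictionary fast path.
    """

    KMER = 5

    def __init__(self, ref: MiRNAReference, params: MatchParams):
        self.params = params
        # records sorted for deterministic tie-breaking
        self.records = sorted(
            ref.records, key=lambda r: (r.mature_id, r.precursor_id)
        )
        self.seqs = [r.mature_sequence.replace("U", "T") for r in self.records]
        self.kmer_index: dict[str, set[int]] = {}
        for idx, s in enumerate(self.seqs):
            for i in range(len(s) - self.KMER + 1):
                self.kmer_index.setdefault(s[i : i + self.KMER], set()).add(idx)
        # exact fast path: reference truncated by (a 5', b 3') bases
        self.trunc: dict[str, list[tuple[int, int, int]]] = {}
        t = params.iso_trim
        t5 = params.iso_trim + params.five_prime_clip
        for idx, s in enumerate(self.seqs):
            for a in range(t5 + 1):
                for b in range(t + 1):
                    key = s[a : len(s) - b] if b else s[a:]
                    self.trunc.setdefault(key, []).append((idx, a, b))

    def _verify(self, read: str, idx: int):
        """Best (mismatches, end_shift) alignment of read vs reference idx."""
        p = self.params
        ref = self.seqs[idx]
        max_miss_5p = p.iso_trim + p.five_prime_clip
        best = None
        for a in range(-p.iso_extend, max_miss_5p + 1):
            # read position i aligns to reference position a + i
            left_over = max(0, -a)  # read bases hanging off the 5' end
            left_miss = max(0, a)  # uncovered reference 5' bases
            end = a + len(read)
            right_over = max(0, end - len(ref))
            right_miss = max(0, len(ref) - end)
            if left_over > p.iso_extend or right_over > p.iso_extend:
                continue
            if left_miss > max_miss_5p or right_miss > p.iso_trim:
                continue
            start_r = left_over
            start_m = a + start_r
            n = min(len(read) - right_over, len(read)) - start_r
            if n <= 0:
                continue
            mm = 0
            seg_r = read[start_r : start_r + n]
            seg_m = ref[start_m : start_m + n]
            if seg_r != seg_m:
                for x, y in zip(seg_r, seg_m):
                    if x != y:
                        mm += 1
                        if mm > p.max_mismatches:
                            break
            if mm > p.max_mismatches:
                continue
            shift = left_over + left_miss + right_over + right_miss
            cand = (mm, shift, a)
            if best is None or cand[:2] < best[:2]:
                best = cand
        return best

    def assign(self, read: str):
        """Return (record_index, mismatches, shift) of best match, or None."""
        p = self.params
        # fast path: strip up to iso_extend 3' overhang bases and look up
        for b_over in range(p.iso_extend + 1):
            key = read[: len(read) - b_over] if b_over else read
            hits = self.trunc.get(key)
            if hits:
                if b_over:
                    # a 3' read overhang cannot coexist with uncovered 3'
                    # reference bases: only b == 0 truncations qualify
                    hits = [h for h in hits if h[2] == 0]
                if hits:
                    idx, a, b = min(hits, key=lambda h: (h[1] + h[2], h[0]))
                    return idx, 0, a + b + b_over
        # candidate generation: probe quarter-point 5-mers
        n = len(read)
        if n < self.KMER:
            return None
        cands: set[int] = set()
        step = max(1, (n - self.KMER) // 3)
        for i in range(0, n - self.KMER + 1, step):
            cands |= self.kmer_index.get(read[i : i + self.KMER], set())
        best = None
        best_idx = None
        for idx in sorted(cands):
            res = self._verify(read, idx)
            if res is None:
                continue
            rec = self.records[idx]
            key = (res[0], res[1], rec.mature_id, rec.precursor_id)
            if best is None or key < best:
                best = key
                best_idx = (idx, res[0], res[1])
        return best_idx


def align_and_count(
    reads_by_library: dict[str, list[tuple[str, str]]],
    ref: MiRNAReference,
    params: MatchParams | None = None,
):
    """Align trimmed reads to the reference and count per precursor.

    Returns ``(CountMatrix, unmapped, stats)`` where unmapped maps library
    -> unassigned reads and stats is a per-library DataFrame with mapped
    counts, perfect-match fraction and a mismatch histogram.
    """
    params = params or MatchParams()
    if not ref.records:
        raise ValueError("empty miRNA reference")
    if not reads_by_library or all(not v for v in reads_by_library.values()):
        logger.warning("empty read set: returning empty count matrix")
    matcher = _Matcher(ref, params)
    features = [(r.precursor_id, r.mature_id) for r in matcher.records]
    feat_ids = [f"{p}|{m}" for p, m in features]
    libs = list(reads_by_library)
    counts = np.zeros((len(features), len(libs)), dtype=int)
    unmapped: dict[str, list[tuple[str, str]]] = {}
    stats_rows = []
    for j, lib in enumerate(libs):
        n_mapped = 0
        mm_hist = np.zeros(params.max_mismatches + 1, dtype=int)
        un = []
        for rid, seq in reads_by_library[lib]:
            hit = matcher.assign(seq)
            if hit is None:
                un.append((rid, seq))
                continue
            idx, mm, _shift = hit
            counts[idx, j] += 1
            n_mapped += 1
            mm_hist[mm] += 1
        unmapped[lib] = un
        total = len(reads_by_library[lib])
        stats_rows.append(
            {
                "library": lib,
                "total": total,
                "mapped": n_mapped,
                "unmapped": total - n_mapped,
                "perfect_fraction": (mm_hist[0] / n_mapped) if n_mapped else 0.0,
                **{f"mm{k}": int(v) for k, v in enumerate(mm_hist)},
            }
        )
    annotations = pd.DataFrame(
        {
            "precursor_id": [p for p, _ in features],
            "mature_id": [m for _, m in features],
            "star_flag": [r.star_flag for r in matcher.records],
        },
        index=feat_ids,
    )
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=feat_ids, columns=libs),
        annotations=annotations,
    )
    return matrix, unmapped, pd.DataFrame(stats_rows).set_index("library")


def align_filter_db(
    unmapped: dict[str, list[tuple[str, str]]],
    filter_ref: MiRNAReference,
    params: MatchParams | None = None,
):
    """Align previously unmapped reads to a filter reference.

    Same matcher as :func:`align_and_count`.  Returns ``(CountMatrix,
    still_unmapped, report)`` where report carries per-library mapped
    percentages and the mismatch histogram.
    """
    matrix, still_unmapped, stats = align_and_count(unmapped, filter_ref, params)
    stats = stats.copy()
    stats["mapped_percent"] = np.where(
        stats["total"] > 0, 100.0 * stats["mapped"] / stats["total"], 0.0
    )
    return matrix, still_unmapped, stats


def merge_counts(matrix: CountMatrix) -> CountMatrix:
    """Sum per-precursor rows sharing a mature sequence into mature rows."""
    ann = matrix.annotations.loc[matrix.counts.index]
    seq_by_mature: dict[str, set] = {}
    if "mature_sequence" in ann.columns:
        for mid, s in zip(ann["mature_id"], ann["mature_sequence"]):
            seq_by_mature.setdefault(mid, set()).add(s)
        bad = [m for m, seqs in seq_by_mature.items() if len(seqs) > 1]
        if bad:
            raise ValueError(f"inconsistent mature sequences for {bad[:5]}")
    grouped = matrix.counts.groupby(ann["mature_id"], sort=True).sum()
    star = ann.groupby("mature_id", sort=True)["star_flag"].first()
    precursors = ann.groupby("mature_id", sort=True)["precursor_id"].apply(
        lambda s: ",".join(sorted(s))
    )
    annotations = pd.DataFrame(
        {"precursor_id": precursors, "mature_id": grouped.index, "star_flag": star},
        index=grouped.index,
    )
    return CountMatrix(
        counts=grouped,
        annotations=annotations,
        norm_factors=matrix.norm_factors.copy(),
        min_count_threshold=matrix.min_count_threshold,
    )


def cpm_filter(
    matrix: CountMatrix, min_cpm: float = 1.0, min_libraries: int = 3
) -> CountMatrix:
    """Keep features with CPM >= min_cpm in >= min_libraries libraries."""
    n_libs = matrix.counts.shape[1]
    if min_libraries > n_libs:
        raise ValueError(
            f"min_libraries={min_libraries} exceeds the {n_libs} available libraries"
        )
    sizes = matrix.library_sizes
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive for CPM filtering")
    cpm = matrix.counts / (sizes * matrix.norm_factors) * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_libraries
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        annotations=matrix.annotations.loc[matrix.counts.index[keep]],
        norm_factors=matrix.norm_factors.copy(),
        min_count_threshold=matrix.min_count_threshold,
    )
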