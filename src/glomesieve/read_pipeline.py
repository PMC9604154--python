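"""Raw reads to representative sequences and a per-sample count table.

Steps: overlap-merge read pairs, expected-error quality filter, size filter
(the 300-470 bp window that retains putative Glomeromycota amplicons),
dereplication, and abundance-greedy centroid clustering at a 0.02 distance
cutoff with vsearch-style identity (matches over alignment columns,
terminal gaps excluded).

Chimera screening is an upstream concern: the pipeline consumes
pre-screened reads and records that provenance, it does not detect chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .primer_scan import reverse_complement  # re-exported convenience

__all__ = [
    "SeqRecord", "ClusterSet", "merge_pairs", "expected_errors",
    "quality_filter", "size_filter", "dereplicate", "cluster_greedy",
    "reverse_complement",
]


@dataclass
class SeqRecord:
    id: str
    sample: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.qualities is not None and \
                len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length != sequence length")

    def __len__(self):
        return len(self.sequence)


def merge_pairs(r1: SeqRecord, r2: SeqRecord, min_overlap: int = 16,
                max_mismatch_frac: float = 0.10) -> SeqRecord | None:
    """Merge a read pair by its best ungapped overlap; None when rejected.

    The reverse read is reverse-complemented, every overlap of at least
    ``min_overlap`` bases is scored by its number of matches, and
    disagreements in the winning overlap are resolved toward the
    higher-quality base. Pairs whose best overlap exceeds
    ``max_mismatch_frac`` mismatches are rejected.
    """
    fwd = r1.sequence.upper()
    rev = reverse_complement(r2.sequence)
    q1 = r1.qualities or [30] * len(fwd)
    q2 = (r2.qualities or [30] * len(r2.sequence))[::-1]
    a = np.frombuffer(fwd.encode(), dtype=np.uint8)
    b = np.frombuffer(rev.encode(), dtype=np.uint8)
    best = None  # (matches, overlap)
    for ov in range(min_overlap, min(len(a), len(b)) + 1):
        matches = int(np.sum(a[len(a) - ov:] == b[:ov]))
        if best is None or matches > best[0] or \
                (matches == best[0] and ov < best[1]):
            best = (matches, ov)
    if best is None:
        return None
    matches, ov = best
    if (ov - matches) / ov > max_mismatch_frac:
        return None
    s = len(a) - ov
    merged = list(fwd[:s])
    quals = list(q1[:s])
    for i in range(ov):
        x, qx = fwd[s + i], q1[s + i]
        y, qy = rev[i], q2[i]
        if x == y:
            merged.append(x)
            quals.append(max(qx, qy))
        elif qx >= qy:
            merged.append(x)
            quals.append(qx)
        else:
            merged.append(y)
            quals.append(qy)
    merged.extend(rev[ov:])
    quals.extend(q2[ov:])
    return SeqRecord(r1.id.removesuffix("/1"), r1.sample, "".join(merged), quals)


def expected_errors(qualities) -> float:
    q = np.asarray(qualities, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def quality_filter(reads, max_expected_errors: float = 1.0):
    """Drop reads whose expected error count exceeds the budget.

    Reads without quality strings pass unfiltered.
    """
    kept, removed = [], 0
    for r in reads:
        if r.qualities is not None and \
                expected_errors(r.qualities) > max_expected_errors:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


def size_filter(reads, min_len: int = 300, max_len: int = 470):
    """Retain reads with min_len <= length <= max_len (bounds inclusive;
    the screen removes reads shorter than 300 bp or longer than 470 bp)."""
    kept, removed = [], 0
    for r in reads:
        if min_len <= len(r) <= max_len:
            kept.append(r)
        else:
            removed += 1
    return kept, removed


# ---------------------------------------------------------------------------
# clustering


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -1.0
    # end gaps free: vsearch-style semi-global identity
    al.end_gap_score = 0.0
    return al


def pairwise_identity(a: str, b: str, aligner=None) -> float:
    """Matches / alignment columns, terminal gaps excluded."""
    if a == b:
        return 1.0
    aligner = aligner or _aligner()
    aln = aligner.align(a, b)[0]
    ta, qa = aln.aligned  # aligned segment coordinates in a and b
    matches = 0
    cols = 0
    prev_end = None
    for (s1, e1), (s2, e2) in zip(ta, qa):
        seg_a, seg_b = a[s1:e1], b[s2:e2]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        cols += e1 - s1
        if prev_end is not None:
            # internal gap columns between consecutive blocks
            cols += (s1 - prev_end[0]) + (s2 - prev_end[1])
        prev_end = (e1, e2)
    if cols == 0:
        return 0.0
    return matches / cols


@dataclass
class ClusterSet:
    """Greedy clusters: representatives, read membership, per-sample counts."""

    representatives: list[SeqRecord]
    membership: dict[str, int]
    counts: pd.DataFrame  # samples x clusters, integer

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def cluster_names(self) -> list[str]:
        return list(self.counts.columns)

    def singletons_per_sample(self) -> pd.Series:
        return (self.counts == 1).sum(axis=1)

    def write_membership(self, path):
        with open(path, "w") as fh:
            fh.write("read_id\tcluster\n")
            for rid, c in sorted(self.membership.items()):
                fh.write(f"{rid}\t{self.counts.columns[c]}\n")


def cluster_greedy(reads: list[SeqRecord], cutoff: float = 0.02) -> ClusterSet:
    """Abundance-greedy centroid clustering.

    Reads are dereplicated and sorted by abundance (descending, ties broken
    lexicographically by sequence); each unique sequence joins the first
    existing centroid with identity >= 1 - cutoff, else founds a new
    centroid. Deterministic given the input multiset.
    """
    if not 0 < cutoff < 0.5:
        raise ValueError("cutoff must be in (0, 0.5)")
    if not reads:
        return ClusterSet([], {}, pd.DataFrame(dtype=int))
    groups = dereplicate(reads)
    order = sorted(groups, key=lambda s: (-len(groups[s]), s))
    aligner = _aligner()
    threshold = 1.0 - cutoff
    # Equal-length pairs are prescreened by Hamming identity: at or above
    # the threshold the gap-free alignment is already optimal for identity;
    # far below it (margin 0.05) gaps cannot bridge the deficit for
    # amplicons of one locus, so the full alignment runs only in the
    # borderline band or for unequal lengths.
    margin = 0.05
    centroids: list[str] = []
    centroid_arrays: list[np.ndarray] = []
    assignment: dict[str, int] = {}
    for seq in order:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        target = None
        for ci, cseq in enumerate(centroids):
            if len(cseq) == len(seq):
                ham = float(np.mean(arr == centroid_arrays[ci]))
                if ham >= threshold:
                    target = ci
                    break
                if ham < threshold - margin:
                    continue
            if pairwise_identity(seq, cseq, aligner) >= threshold:
                target = ci
                break
        if target is None:
            centroids.append(seq)
            centroid_arrays.append(arr)
            target = len(centroids) - 1
        assignment[seq] = target
    membership = {}
    count_rows: dict[str, np.ndarray] = {}
    samples = []
    for r in reads:
        c = assignment[r.sequence.upper()]
        membership[r.id] = c
        if r.sample not in count_rows:
            count_rows[r.sample] = np.zeros(len(centroids), dtype=int)
            samples.append(r.sample)
        count_rows[r.sample][c] += 1
    names = [f"OTU{c + 1:04d}" for c in range(len(centroids))]
    counts = pd.DataFrame([count_rows[s] for s in samples], index=samples,
                          columns=names)
    counts.index.name = "sample"
    reps = []
    for ci, cseq in enumerate(centroids):
        first = next(r for r in reads if r.sequence.upper() == cseq)
        reps.append(SeqRecord(names[ci], first.sample, cseq))
    return ClusterSet(reps, membership, counts)


def dereplicate(reads) -> dict[str, list[str]]:
    """Unique sequence -> list of read ids (uppercased comparison)."""
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.sequence.upper(), []).append(r.id)
    return groups


def run_pipeline(reads, min_len: int = 300, max_len: int = 470,
                 cutoff: float = 0.02, max_expected_errors: float = 1.0):
    """Quality filter -> size filter -> greedy clustering; returns
    (ClusterSet, stats dict)."""
    kept, n_quality = quality_filter(reads, max_expected_errors)
    kept, n_size = size_filter(kept, min_len, max_len)
    clusters = cluster_greedy(kept, cutoff)
    stats = {"input": len(reads), "removed_quality": n_quality,
             "removed_size": n_size, "retained": len(kept),
             "clusters": clusters.n_clusters}
    return clusters, stats
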