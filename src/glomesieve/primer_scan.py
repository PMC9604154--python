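"""In-silico PCR with 3'-anchored mismatch tolerance and length windows.

The screening strategy: primers anneal permissively (up to ``max_mismatches``
mismatches tolerated, but none within the 3'-terminal ``protected_3prime``
residues) and target specificity comes from the amplicon length window
rather than primer specificity. IUPAC degeneracy on either side counts as a
match whenever the two code sets intersect.

Coordinates are 0-based half-open internally; report helpers convert to
1-based inclusive (GenBank style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import IUPAC_MASKS

#: Illumina adapter prefixes that may decorate sequencing primers; stripped
#: before scanning because they are non-genomic.
ADAPTER_PREFIXES = (
    "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG",
    "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG",
)

_COMPLEMENT = str.maketrans("ACGTUMRWSYKVHDBN-.", "TGCAAKYWSRMBDHVN-.")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str, what: str) -> np.ndarray:
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        mask = IUPAC_MASKS.get(ch)
        if mask is None or ch in "-.":
            raise ValueError(f"non-IUPAC character {ch!r} in {what} at {i}")
        out[i] = mask
    return out


@dataclass
class PrimerSpec:
    """An IUPAC primer (5'->3') with its mismatch budget.

    ``max_mismatches`` mismatches are tolerated anywhere except within the
    ``protected_3prime`` residues closest to the 3' end, where none are.
    Known sequencing-adapter prefixes are stripped at construction.
    """

    name: str
    sequence: str
    max_mismatches: int = 3
    protected_3prime: int = 5

    def __post_init__(self):
        seq = self.sequence.upper().replace(" ", "")
        for adapter in ADAPTER_PREFIXES:
            if seq.startswith(adapter):
                seq = seq[len(adapter):]
        if not seq:
            raise ValueError("primer sequence is empty")
        bad = set(seq) - set(IUPAC_MASKS) | (set(seq) & {"-", "."})
        if bad:
            raise ValueError(f"non-IUPAC characters in primer: {bad}")
        if self.protected_3prime > len(seq):
            raise ValueError("protected 3' zone longer than the primer")
        self.sequence = seq

    def __len__(self):
        return len(self.sequence)


@dataclass
class AmpliconHit:
    """One forward/reverse primer pairing on the plus strand."""

    template_id: str
    fwd_start: int   # 0-based
    rev_end: int     # 0-based half-open
    fwd_mismatches: int
    rev_mismatches: int
    window_label: str = ""

    @property
    def length(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def fwd_start_1based(self) -> int:
        return self.fwd_start + 1


def _scan(template_masks: np.ndarray, pattern_masks: np.ndarray,
          max_mismatches: int, protected: np.ndarray) -> list[tuple[int, int]]:
    """All start positions where the pattern binds.

    ``protected`` is a boolean array over pattern positions where no
    mismatch is allowed. A position matches when the IUPAC code sets
    intersect.
    """
    n, m = len(template_masks), len(pattern_masks)
    if n < m:
        raise ValueError("template shorter than primer")
    windows = np.lib.stride_tricks.sliding_window_view(template_masks, m)
    mism = (windows & pattern_masks[None, :]) == 0
    total = mism.sum(axis=1)
    in_protected = mism[:, protected].any(axis=1) if protected.any() else \
        np.zeros(n - m + 1, dtype=bool)
    ok = (total <= max_mismatches) & ~in_protected
    return [(int(i), int(total[i])) for i in np.flatnonzero(ok)]


def find_binding_sites(template: str, primer: PrimerSpec,
                       strand: str = "plus") -> list[tuple[int, int]]:
    """Binding sites of ``primer`` on one strand of ``template``.

    Returns ``(start, mismatches)`` pairs, 0-based on the plus strand and
    sorted ascending. For the minus strand the reverse complement of the
    primer is scanned on the plus strand; the protected 3' zone then lies at
    the *start* of the scanned pattern.
    """
    if strand not in ("plus", "minus"):
        raise ValueError("strand must be 'plus' or 'minus'")
    tmpl = _encode(template, "template")
    m = len(primer)
    protected = np.zeros(m, dtype=bool)
    if strand == "plus":
        pattern = _encode(primer.sequence, "primer")
        if primer.protected_3prime:
            protected[m - primer.protected_3prime:] = True
    else:
        pattern = _encode(reverse_complement(primer.sequence), "primer")
        if primer.protected_3prime:
            protected[: primer.protected_3prime] = True
    return _scan(tmpl, pattern, primer.max_mismatches, protected)


def extract_amplicons(template: str, fwd: PrimerSpec, rev: PrimerSpec,
                      min_len: int = 330, max_len: int = 480,
                      template_id: str = "template",
                      length_ceiling: int = 2000) -> list[AmpliconHit]:
    """Pair plus-strand forward sites with downstream minus-strand reverse
    sites; every pairing up to ``length_ceiling`` bp is reported.

    The amplicon spans the forward primer's 5' start through the reverse
    primer's 5' start, inclusive of both primer sequences.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    fwd_sites = find_binding_sites(template, fwd, "plus")
    rev_sites = find_binding_sites(template, rev, "minus")
    hits = []
    for fs, fm in fwd_sites:
        for rs, rm in rev_sites:
            rev_end = rs + len(rev)   # reverse primer 5' end, plus strand
            length = rev_end - fs
            if length <= 0 or length > length_ceiling:
                continue
            if length < min_len:
                label = "below-window"
            elif length > max_len:
                label = "above-window"
            else:
                label = "target-window"
            hits.append(AmpliconHit(template_id, fs, rev_end, fm, rm, label))
    hits.sort(key=lambda h: (h.fwd_start, h.rev_end))
    return hits


def screen_dataset(sequences: dict[str, str], groups: dict[str, str],
                   fwd: PrimerSpec, rev: PrimerSpec,
                   min_len: int = 330, max_len: int = 480,
                   on_unlabeled: str = "skip") -> pd.DataFrame:
    """Amplicon length summary per sequence group.

    Parameters
    ----------
    sequences : id -> DNA string (e.g. read from FASTA)
    groups : id -> group label
    on_unlabeled : 'skip' (drop with a warning) or 'fail'

    Returns a per-group table with sequence/amplicon counts, length extrema
    (annotated with the sequence ids attaining them), median length, and the
    fraction of amplicons inside the target window.
    """
    if not sequences:
        raise ValueError("no sequences to screen")
    import warnings
    rows = {}
    for sid, seq in sequences.items():
        if sid not in groups:
            if on_unlabeled == "fail":
                raise ValueError(f"sequence {sid!r} has no group label")
            warnings.warn(f"skipping unlabeled sequence {sid!r}")
            continue
        g = groups[sid]
        entry = rows.setdefault(g, {"n_sequences": 0, "lengths": [],
                                    "ids": []})
        entry["n_sequences"] += 1
        for hit in extract_amplicons(seq, fwd, rev, min_len, max_len,
                                     template_id=sid):
            entry["lengths"].append(hit.length)
            entry["ids"].append(sid)
    if not rows:
        raise ValueError("no labelled sequences to screen")
    out = []
    for g in sorted(rows):
        entry = rows[g]
        lengths = np.asarray(entry["lengths"])
        if lengths.size:
            imin, imax = int(lengths.argmin()), int(lengths.argmax())
            in_window = float(np.mean((lengths >= min_len) &
                                      (lengths <= max_len)))
            out.append({
                "group": g, "n_sequences": entry["n_sequences"],
                "n_amplicons": int(lengths.size),
                "len_min": int(lengths.min()),
                "len_min_id": entry["ids"][imin],
                "len_max": int(lengths.max()),
                "len_max_id": entry["ids"][imax],
                "len_median": float(np.median(lengths)),
                "fraction_in_window": in_window,
            })
        else:
            out.append({"group": g, "n_sequences": entry["n_sequences"],
                        "n_amplicons": 0, "len_min": np.nan,
                        "len_min_id": "", "len_max": np.nan,
                        "len_max_id": "", "len_median": np.nan,
                        "fraction_in_window": np.nan})
    return pd.DataFrame(out).set_index("group")
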