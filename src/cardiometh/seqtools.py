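"""Sequence-level utilities: CpG-island detection and bisulfite simulation.

CpG islands are detected with the classic sliding-window scheme of Takai &
Jones: a window qualifies when it is long enough, GC-rich enough and has a
high enough observed/expected CpG ratio. The two composition criteria can be
combined conjunctively (canonical) or disjunctively, because loosely defined
"islands" that satisfy only one criterion are biologically relevant for some
promoters. Bisulfite conversion is simulated at the sequence level:
unmethylated cytosines deaminate to uracil and are read as thymine, while
methylated CpG cytosines are protected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CGIInterval",
    "CloneCalls",
    "gc_content",
    "cpg_obs_exp",
    "cpg_positions",
    "find_cgis",
    "bisulfite_convert",
    "call_clone_methylation",
]

_VALID = set("ACGTN")


def _check_seq(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class CGIInterval:
    """A CpG island on the input sequence, 0-based half-open coordinates."""

    start: int
    end: int
    gc_fraction: float
    cpg_obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CloneCalls:
    """Per-CpG methylation calls for one bisulfite clone.

    ``calls`` maps reference CpG cytosine position -> 'M' (methylated),
    'U' (unmethylated) or 'N' (uncallable). ``conversion_efficiency`` is the
    fraction of non-CpG reference cytosines read as thymine; values near 0
    indicate failed bisulfite conversion.
    """

    calls: dict[int, str]
    conversion_efficiency: float


def gc_content(seq: str) -> float:
    """Fraction of G+C among non-N bases.

    Raises ``ValueError`` for empty or all-N input.
    """
    s = _check_seq(seq)
    n_informative = len(s) - s.count("N")
    if n_informative == 0:
        raise ValueError("sequence empty or all N")
    return (s.count("G") + s.count("C")) / n_informative


def cpg_obs_exp(seq: str) -> float:
    """Observed/expected CpG ratio: (#CpG * length) / (#C * #G).

    Returns 0 when the sequence contains no C or no G. CpG dinucleotides are
    counted by a left-to-right non-overlapping scan.
    """
    s = _check_seq(seq)
    if len(s) < 2:
        raise ValueError("sequence shorter than 2 bp")
    n_c = s.count("C")
    n_g = s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return s.count("CG") * len(s) / (n_c * n_g)


def cpg_positions(seq: str) -> list[int]:
    """0-based positions of CpG cytosines."""
    s = _check_seq(seq)
    return [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]


def _meets(seq: str, min_gc: float, min_oe: float, combine: str) -> bool:
    gc_ok = gc_content(seq) >= min_gc if set(seq) != {"N"} else False
    oe_ok = cpg_obs_exp(seq) >= min_oe
    if combine == "AND":
        return gc_ok and oe_ok
    return gc_ok or oe_ok


def find_cgis(
    seq: str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
    step: int = 1,
    combine: str = "AND",
) -> list[CGIInterval]:
    """Detect CpG islands by a sliding-window scan.

    Every window of ``window`` bp (advanced by ``step``) is tested against the
    GC-content and observed/expected-CpG criteria, joined by ``combine``
    ("AND" is the canonical conjunction, "OR" admits regions meeting a single
    criterion). Overlapping or adjacent qualifying windows are merged; each
    merged interval is re-checked and, if it no longer satisfies the
    criteria, trimmed one base at a time (alternating 3' then 5' end) until
    it does or drops below ``min_length`` (in which case it is discarded).
    Output is deterministic and sorted by start.
    """
    s = _check_seq(seq)
    if combine not in ("AND", "OR"):
        raise ValueError("combine must be 'AND' or 'OR'")
    if window > len(s):
        raise ValueError(f"window ({window}) exceeds sequence length ({len(s)})")
    if window < min_length:
        raise ValueError("window must be >= min_length")
    hits = [
        (i, i + window)
        for i in range(0, len(s) - window + 1, step)
        if _meets(s[i : i + window], min_gc, min_oe, combine)
    ]
    # merge overlapping/adjacent windows
    merged: list[list[int]] = []
    for a, b in hits:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out: list[CGIInterval] = []
    for a, b in merged:
        a, b = _trim(s, a, b, min_length, min_gc, min_oe, combine)
        if a is not None:
            sub = s[a:b]
            out.append(CGIInterval(a, b, gc_content(sub), cpg_obs_exp(sub)))
    return out


def _trim(seq, a, b, min_length, min_gc, min_oe, combine):
    """Shrink [a, b) until it meets the criteria; alternate right/left trims."""
    from_right = True
    while b - a >= min_length:
        if _meets(seq[a:b], min_gc, min_oe, combine):
            return a, b
        if from_right:
            b -= 1
        else:
            a += 1
        from_right = not from_right
    return None, None


def bisulfite_convert(
    seq: str,
    methylated_cpg_positions: set[int] | list[int],
    conversion_rate: float = 1.0,
    seed: int | None = None,
) -> str:
    """Simulate bisulfite treatment of ``seq``.

    Cytosines outside methylated CpG sites convert to thymine with
    probability ``conversion_rate`` (unmethylated CpG cytosines included);
    methylated CpG cytosines and all other bases are untouched. Every listed
    position must be the C of a CpG dinucleotide.
    """
    s = _check_seq(seq)
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in [0, 1]")
    meth = set(methylated_cpg_positions)
    valid = set(cpg_positions(s))
    bad = meth - valid
    if bad:
        raise ValueError(f"positions are not CpG cytosines: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    out = list(s)
    for i, base in enumerate(out):
        if base == "C" and i not in meth:
            if conversion_rate >= 1.0 or rng.random() < conversion_rate:
                out[i] = "T"
    return "".join(out)


def call_clone_methylation(ref_seq: str, clone_seq: str) -> CloneCalls:
    """Call per-CpG methylation of a bisulfite clone against its reference.

    The clone must be pre-aligned (equal length). At each reference CpG
    cytosine, clone C means methylated, T unmethylated, anything else
    uncallable. Conversion efficiency is the fraction of non-CpG reference
    cytosines read as T; an efficiency of 0 on a clone identical to the
    reference flags failed conversion rather than full methylation.
    """
    ref = _check_seq(ref_seq)
    clone = _check_seq(clone_seq)
    if len(ref) != len(clone):
        raise ValueError(f"length mismatch: ref {len(ref)} vs clone {len(clone)}")
    cpgs = set(cpg_positions(ref))
    calls = {}
    for i in sorted(cpgs):
        base = clone[i]
        calls[i] = "M" if base == "C" else "U" if base == "T" else "N"
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpgs]
    if non_cpg_c:
        eff = sum(clone[i] == "T" for i in non_cpg_c) / len(non_cpg_c)
    else:
        eff = float("nan")
    return CloneCalls(calls=calls, conversion_efficiency=eff)
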