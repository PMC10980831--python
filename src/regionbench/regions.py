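"""In-silico PCR: primer matching and variable-region amplicon extraction.

The six amplicons benchmarked downstream (V1-V3, V3-V4, V4, V4-V5, V6-V8,
V6-V9) are defined operationally by degenerate primer pairs.  Matching is
IUPAC-aware, tolerates a configurable number of mismatches, but insists on a
perfect match in the primer's 3'-terminal 5 bases — polymerase extension
starts there, so real PCR is far less forgiving at that end.

Coordinates are 0-based half-open internally; the drop report and other
human-facing tables use 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AmpliconLengthError, InvalidArgument, NoAmplicon
from .records import IUPAC_SETS, SequenceRecord, reverse_complement

__all__ = [
    "PrimerPair", "RegionHit", "DEFAULT_PANEL", "match_primer",
    "extract_region", "choose_copy", "extract_panel", "PanelResult",
]

#: How many 3'-terminal primer bases must match exactly.
THREE_PRIME_WINDOW = 5

#: Accepted amplicon-interior length range (bases).
MIN_AMPLICON, MAX_AMPLICON = 50, 1200


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair naming one variable-region amplicon.

    ``forward`` is written 5'->3' on the plus strand, ``reverse`` 5'->3' on
    the minus strand (the usual primer-catalog convention).
    """

    region_label: str
    forward: str
    reverse: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward),
                             ("reverse", self.reverse)):
            if not primer:
                raise InvalidArgument(f"{name} primer is empty")
            bad = set(primer.upper()) - set(IUPAC_SETS)
            if bad:
                raise InvalidArgument(
                    f"{name} primer {primer!r} has non-IUPAC codes {bad}")
        if self.max_mismatch < 0:
            raise InvalidArgument("max_mismatch must be >= 0")


@dataclass
class RegionHit:
    """One extracted amplicon interior (primers excluded)."""

    genome_id: str
    region_label: str
    start: int
    end: int
    sequence: str
    fwd_mismatches: int
    rev_mismatches: int


#: Standard primer pairs for the six benchmarked windows.  These are the
#: commonly used pairs for the named windows (27F/534R, 341F/805R, 515F/806R,
#: 515F/926R, 926F/1392R, 926F/1492R); any panel can be substituted via TSV.
DEFAULT_PANEL: tuple[PrimerPair, ...] = (
    PrimerPair("V1-V3", "AGAGTTTGATCMTGGCTCAG", "ATTACCGCGGCTGCTGG"),
    PrimerPair("V3-V4", "CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC"),
    PrimerPair("V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT"),
    PrimerPair("V4-V5", "GTGYCAGCMGCCGCGGTAA", "CCGYCAATTYMTTTRAGTTT"),
    PrimerPair("V6-V8", "AAACTYAAAKGAATTGRCGG", "ACGGGCGGTGTGTRC"),
    PrimerPair("V6-V9", "AAACTYAAAKGAATTGRCGG", "TACGGYTACCTTGTTACGACTT"),
)

#: Fixed ordering of the default panel, used for tie-breaks downstream.
PANEL_ORDER: tuple[str, ...] = tuple(p.region_label for p in DEFAULT_PANEL)


# ---------------------------------------------------------------------------
# matching

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}

# compatibility[iupac_code_index, base_index] -> bool
_CODE_LIST = "ACGTRYSWKMBDHVN"
_CODE_INDEX = {c: i for i, c in enumerate(_CODE_LIST)}
_COMPAT = np.zeros((len(_CODE_LIST), 4), dtype=bool)
for _c, _i in _CODE_INDEX.items():
    for _b in IUPAC_SETS[_c]:
        _COMPAT[_i, _BASE_CODE[_b]] = True

_SEQ_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_CODE.items():
    _SEQ_LUT[ord(_b)] = _i


def _encode_plain(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; ambiguity codes and gaps become -1 (which
    never satisfies a primer position, a conservative choice)."""
    return _SEQ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def match_primer(seq: str, primer: str, max_mismatch: int,
                 strand: str = "+") -> list[tuple[int, int]]:
    """All placements of ``primer`` on ``seq`` with at most ``max_mismatch``
    mismatches and a perfect 3'-terminal 5-base match.

    For ``strand="-"`` the primer is reverse-complemented first, so returned
    positions are footprint starts on the plus strand either way.  The
    3'-terminal window of a minus-strand primer corresponds to the *first*
    bases of its plus-strand footprint.

    Returns ``(position, mismatches)`` tuples sorted by position.
    """
    if not primer:
        raise InvalidArgument("empty primer")
    if not seq:
        raise InvalidArgument("empty sequence")
    if strand not in "+-":
        raise InvalidArgument(f"strand must be '+' or '-', got {strand!r}")
    primer = primer.upper()
    if strand == "-":
        pattern = reverse_complement(primer)
        three_prime = slice(0, THREE_PRIME_WINDOW)
    else:
        pattern = primer
        three_prime = slice(max(0, len(primer) - THREE_PRIME_WINDOW),
                            len(primer))
    m, n = len(pattern), len(seq)
    if m >= n:
        return []

    enc = _encode_plain(seq.upper())
    codes = np.array([_CODE_INDEX[c] for c in pattern])
    n_windows = n - m + 1
    # mismatch[i, j]: pattern position j vs seq position i + j
    windows = np.lib.stride_tricks.sliding_window_view(enc, m)
    ok = np.where(windows >= 0, _COMPAT[codes[None, :], windows], False)
    mism = m - ok.sum(axis=1)
    strict = ok[:, three_prime].all(axis=1)
    hits = np.nonzero((mism <= max_mismatch) & strict)[0]
    return [(int(i), int(mism[i])) for i in hits]


# ---------------------------------------------------------------------------
# extraction


def extract_region(record: SequenceRecord, pair: PrimerPair) -> RegionHit:
    """Extract one amplicon interior from a 16S sequence.

    Uses the leftmost forward footprint and the rightmost reverse footprint
    to its right; the returned interval lies strictly between the two primer
    footprints.  Raises :class:`NoAmplicon` / :class:`AmpliconLengthError`
    when placement fails.
    """
    seq = record.seq.upper()
    fwd_hits = match_primer(seq, pair.forward, pair.max_mismatch, "+")
    if not fwd_hits:
        raise NoAmplicon(record.genome_id, pair.region_label,
                         "no forward primer site")
    fpos, fmm = fwd_hits[0]
    fend = fpos + len(pair.forward)
    rev_hits = [(p, mm) for p, mm in
                match_primer(seq, pair.reverse, pair.max_mismatch, "-")
                if p >= fend]
    if not rev_hits:
        raise NoAmplicon(record.genome_id, pair.region_label,
                         "no reverse primer site right of the forward site")
    rpos, rmm = rev_hits[-1]
    start, end = fend, rpos
    length = end - start
    if not (MIN_AMPLICON <= length <= MAX_AMPLICON):
        raise AmpliconLengthError(record.genome_id, pair.region_label,
                                  length, MIN_AMPLICON, MAX_AMPLICON)
    return RegionHit(record.genome_id, pair.region_label, start, end,
                     seq[start:end], fmm, rmm)


def choose_copy(copies: list[SequenceRecord]) -> SequenceRecord:
    """Pick one 16S copy per genome: the longest, ties broken by the
    lexicographically smallest sequence id."""
    if not copies:
        raise InvalidArgument("choose_copy: empty copy list")
    return min(copies, key=lambda r: (-len(r.seq), r.id))


@dataclass
class PanelResult:
    """Per-region hits plus a drop report.

    ``drops`` rows are (genome_id, region_label, reason).  A genome dropped
    in one region is still reported for every region where extraction
    succeeded.
    """

    hits: dict[str, list[RegionHit]] = field(default_factory=dict)
    drops: list[tuple[str, str, str]] = field(default_factory=list)

    def hit_genomes(self, region_label: str) -> list[str]:
        return [h.genome_id for h in self.hits.get(region_label, [])]


def extract_panel(ssu: list[SequenceRecord],
                  panel: tuple[PrimerPair, ...] = DEFAULT_PANEL
                  ) -> PanelResult:
    """Run every primer pair against every genome's chosen 16S copy."""
    by_genome: dict[str, list[SequenceRecord]] = {}
    for rec in ssu:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    chosen = {gid: choose_copy(copies)
              for gid, copies in sorted(by_genome.items())}

    result = PanelResult(hits={p.region_label: [] for p in panel} if ssu
                         else {})
    for pair in panel:
        if not ssu:
            break
        for gid, rec in chosen.items():
            try:
                result.hits[pair.region_label].append(
                    extract_region(rec, pair))
            except (NoAmplicon, AmpliconLengthError) as exc:
                result.drops.append((gid, pair.region_label, str(exc)))
    return result
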