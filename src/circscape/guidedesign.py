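"""Design of BSJ-targeting knockdown constructs and off-target screening.

Because a circRNA shares its entire sequence with its linear host except
for the back-splice junction, a knockdown guide must straddle the BSJ to
be circle-specific. Two construct families are supported:

* agoshRNA — a short hairpin processed by AGO2 (no passenger strand),
  assembled with an A at the transcriptional start of the U6 promoter, an
  A-C mismatch at the base of the stem, a poly-T termination signal and
  BbsI cloning overhangs;
* shRNA pair — two 21-nt hairpins whose target windows are shifted 3 nt
  up- and downstream of the junction, each with a vendor loop, an XhoI
  site and a termination signal.

Mature guides are screened against a transcript set with a seeded,
ungapped mismatch scan (exact seed word + mismatch count criterion; no
E-values), and hits can be intersected with a differential-gene list to
flag putative off-target explanations for expression changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BsjTarget",
    "GuideConstruct",
    "OffTargetHit",
    "build_bsj_target",
    "design_shrna_pair",
    "design_agoshrna",
    "offtarget_scan",
    "cross_reference_offtargets",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
DEFAULT_LOOP = "TTCAAGAGA"          # classic pSUPER-style shRNA loop
DEFAULT_AGO_LOOP = "CCACC"          # compact agoshRNA loop
XHOI_SITE = "CTCGAG"
DEFAULT_TERMINATION = "TTTTTT"      # pol III termination signal
DEFAULT_OVERHANGS = ("ACCG", "AAAC")  # BbsI overhangs for U6 vectors
MODEL_PREFIXES = ("XM_", "XR_", "XP_")


class SequenceError(ValueError):
    """Non-ACGT input or a sequence too short for the requested design."""


class DesignError(ValueError):
    """Requested windows/stems cannot cover the junction."""


def _check_dna(seq: str, what: str = "sequence") -> str:
    s = seq.upper().replace("U", "T")
    if not s or any(ch not in "ACGT" for ch in s):
        raise SequenceError(f"{what} must be nonempty ACGT, got {seq!r}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BsjTarget:
    """Sequence context around one back-splice junction.

    ``junction_seq = upstream_seq + downstream_seq`` where ``upstream_seq``
    is the 3' end of the circle's last exon (donor side) and
    ``downstream_seq`` the 5' start of its first exon (acceptor side);
    ``junction`` indexes the first downstream base.
    """

    circ_id: str
    upstream_seq: str
    downstream_seq: str

    @property
    def junction_seq(self) -> str:
        return self.upstream_seq + self.downstream_seq

    @property
    def junction(self) -> int:
        return len(self.upstream_seq)


@dataclass
class GuideConstruct:
    """A designed knockdown construct with its recorded features.

    ``features`` maps feature names to (start, end) positions in
    ``full_insert`` (0-based half-open); every recorded feature is
    literally present at its position. ``offset_nt`` records the signed
    shift of each target-window center from the junction.
    """

    kind: str                                # "agoshRNA" | "shRNA_pair"
    circ_id: str
    target_windows: list[tuple[int, int]]
    guide_seqs: list[str]                    # RNA-sense (ACGU)
    loop_seq: str
    full_insert: str                         # DNA top strand
    bottom_strand: str
    features: dict[str, tuple[int, int]]
    spans_junction: list[bool]
    offset_nt: list[int]
    substitutions: list[str] = field(default_factory=list)
    valid: bool = True

    def feature_seq(self, name: str) -> str:
        lo, hi = self.features[name]
        return self.full_insert[lo:hi]


@dataclass(frozen=True)
class OffTargetHit:
    transcript_id: str
    position: int
    strand: str
    mismatches: int
    matched_span: str


def build_bsj_target(
    circ_exon_seqs: list[str], flank: int, circ_id: str = "circ"
) -> BsjTarget:
    """Assemble the junction context from a circle's exon sequences.

    Back-splicing joins the 3' end of the *last* exon to the 5' start of
    the *first* exon, so the junction window takes the final ``flank`` nt
    of the last exon followed by the initial ``flank`` nt of the first. A
    single-exon circle wraps onto itself.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not circ_exon_seqs:
        raise SequenceError("need at least one exon sequence")
    exons = [_check_dna(s, "exon") for s in circ_exon_seqs]
    last, first = exons[-1], exons[0]
    if flank > len(last) or flank > len(first):
        raise ValueError(
            f"flank {flank} exceeds exon length ({len(last)}/{len(first)})"
        )
    return BsjTarget(
        circ_id=circ_id,
        upstream_seq=last[-flank:],
        downstream_seq=first[:flank],
    )


def _window_at(center: int, window_len: int, junction: int, seq_len: int):
    half = window_len // 2
    start = center - half
    end = start + window_len
    if start < 0 or end > seq_len:
        raise DesignError(
            f"window [{start},{end}) falls outside the junction sequence"
        )
    # the junction boundary sits between junction-1 and junction
    if not (start < junction < end):
        raise DesignError(
            f"window [{start},{end}) does not span the junction at {junction}"
        )
    return start, end


def _to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def design_shrna_pair(
    target: BsjTarget,
    window_len: int = 21,
    offsets: tuple[int, int] = (-3, 3),
    loop_seq: str = DEFAULT_LOOP,
    add_xhoi: bool = True,
    termination: str = DEFAULT_TERMINATION,
) -> list[GuideConstruct]:
    """Design the two-hairpin shRNA pair straddling the junction.

    Each hairpin targets a ``window_len`` window whose center is shifted by
    one of ``offsets`` from the junction (both windows still span it);
    hairpin insert = sense window + loop + antisense + XhoI site +
    termination signal. Returns one construct per offset.
    """
    loop = _check_dna(loop_seq, "loop")
    term = _check_dna(termination, "termination")
    seq = target.junction_seq
    constructs = []
    for offset in offsets:
        start, end = _window_at(
            target.junction + offset, window_len, target.junction, len(seq)
        )
        sense = seq[start:end]
        antisense = reverse_complement(sense)
        insert = sense + loop + antisense
        features = {
            "sense": (0, len(sense)),
            "loop": (len(sense), len(sense) + len(loop)),
            "antisense": (len(sense) + len(loop), len(insert)),
        }
        if add_xhoi:
            features["xhoi"] = (len(insert), len(insert) + len(XHOI_SITE))
            insert += XHOI_SITE
        features["termination"] = (len(insert), len(insert) + len(term))
        insert += term
        constructs.append(
            GuideConstruct(
                kind="shRNA_pair",
                circ_id=target.circ_id,
                target_windows=[(start, end)],
                guide_seqs=[_to_rna(antisense)],
                loop_seq=loop,
                full_insert=insert,
                bottom_strand=reverse_complement(insert),
                features=features,
                spans_junction=[start < target.junction < end],
                offset_nt=[offset],
                valid=insert.count(XHOI_SITE) == (1 if add_xhoi else 0),
            )
        )
    return constructs


def design_agoshrna(
    target: BsjTarget,
    stem_len: int = 18,
    loop_seq: str = DEFAULT_AGO_LOOP,
    overhangs: tuple[str, str] = DEFAULT_OVERHANGS,
    termination: str = DEFAULT_TERMINATION,
    min_side: int = 5,
) -> GuideConstruct:
    """Design an AGO2-processed hairpin centered on the junction.

    The sense stem is the ``stem_len`` window centered on the junction
    (>= ``min_side`` nt on each side). The first transcribed base is forced
    to A (U6 +1 preference; a substitution is recorded if the template base
    differed), one A-C mismatch is placed at the stem base — the antisense
    3' position pairing the +1 A — a poly-T signal terminates transcription
    and BbsI overhangs flank the annealed oligo duplex.
    """
    loop = _check_dna(loop_seq, "loop")
    term = _check_dna(termination, "termination")
    top_oh = _check_dna(overhangs[0], "overhang")
    bottom_oh = _check_dna(overhangs[1], "overhang")
    seq = target.junction_seq
    start, end = _window_at(target.junction, stem_len, target.junction, len(seq))
    if target.junction - start < min_side or end - target.junction < min_side:
        raise DesignError(
            f"stem must leave >= {min_side} nt on each side of the junction"
        )

    sense = seq[start:end]
    substitutions = []
    if sense[0] != "A":
        substitutions.append(f"+1 {sense[0]}>A (U6 transcriptional start)")
        sense = "A" + sense[1:]
    antisense = list(reverse_complement(sense))
    # A-C mismatch below the stem: the antisense base pairing the +1 A
    mismatch_pos_in_anti = len(antisense) - 1
    if antisense[mismatch_pos_in_anti] != "C":
        substitutions.append(
            f"stem-base {antisense[mismatch_pos_in_anti]}>C (A-C mismatch)"
        )
        antisense[mismatch_pos_in_anti] = "C"
    antisense = "".join(antisense)

    hairpin = sense + loop + antisense
    features = {
        "sense_stem": (0, len(sense)),
        "loop": (len(sense), len(sense) + len(loop)),
        "antisense_stem": (len(sense) + len(loop), len(hairpin)),
        "plus_one_A": (0, 1),
        "ac_mismatch": (
            len(sense) + len(loop) + mismatch_pos_in_anti,
            len(sense) + len(loop) + mismatch_pos_in_anti + 1,
        ),
        "termination": (len(hairpin), len(hairpin) + len(term)),
    }
    insert = hairpin + term
    top = top_oh + insert
    bottom = bottom_oh + reverse_complement(insert)
    # shift recorded positions past the top overhang
    features = {
        k: (lo + len(top_oh), hi + len(top_oh)) for k, (lo, hi) in features.items()
    }
    features["bbsi_overhang_top"] = (0, len(top_oh))
    return GuideConstruct(
        kind="agoshRNA",
        circ_id=target.circ_id,
        target_windows=[(start, end)],
        guide_seqs=[_to_rna(antisense)],
        loop_seq=loop,
        full_insert=top,
        bottom_strand=bottom,
        features=features,
        spans_junction=[start < target.junction < end],
        offset_nt=[0],
        substitutions=substitutions,
    )


def _max_run(matches: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    best = run = 0
    for m in matches:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def offtarget_scan(
    guide: str,
    transcripts: list[tuple[str, str]],
    max_mismatch: int = 2,
    min_word: int = 7,
    exclude_prefixes: tuple[str, ...] = MODEL_PREFIXES,
) -> list[OffTargetHit]:
    """Scan transcripts for near-complementary sites of a mature guide.

    A hit is an ungapped alignment of the guide's full target site
    (reverse complement of the guide) with at most ``max_mismatch``
    mismatches that contains at least one exact run of ``min_word``
    matches (the seed requirement). Both strands of every transcript are
    scanned; hits are unique per (transcript, position, strand). Model
    transcripts (ids matching ``exclude_prefixes``) are skipped.
    ``position`` is 0-based on the '+' strand of the transcript.
    """
    if not guide:
        raise ValueError("empty guide")
    g = _check_dna(guide, "guide")
    if len(g) < min_word:
        raise ValueError(f"guide shorter than min_word={min_word}")
    site = reverse_complement(g)  # the sequence the guide base-pairs with
    L = len(site)
    site_arr = _encode(site)

    hits: dict[tuple[str, int, str], OffTargetHit] = {}
    for tid, seq in transcripts:
        if tid.startswith(exclude_prefixes):
            continue
        seq = seq.upper().replace("U", "T")
        if len(seq) < L:
            continue
        for strand in ("+", "-"):
            s = seq if strand == "+" else reverse_complement(seq)
            arr = _encode(s)
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            matches = windows == site_arr
            mm = L - matches.sum(axis=1)
            for idx in np.nonzero(mm <= max_mismatch)[0]:
                if _max_run(matches[idx]) < min_word:
                    continue
                # report position on the '+' strand coordinates
                pos = idx if strand == "+" else len(seq) - L - idx
                key = (tid, int(pos), strand)
                if key not in hits:
                    hits[key] = OffTargetHit(
                        transcript_id=tid,
                        position=int(pos),
                        strand=strand,
                        mismatches=int(mm[idx]),
                        matched_span=s[idx : idx + L],
                    )
    return sorted(
        hits.values(), key=lambda h: (h.transcript_id, h.position, h.strand)
    )


def cross_reference_offtargets(
    hits: list[OffTargetHit], deg_ids, id_map: dict[str, str] | None = None
) -> set[str]:
    """DEG ids that are also putative off-target genes.

    ``id_map`` translates transcript ids to gene ids when the two lists use
    different namespaces; by default transcript ids are compared directly.
    """
    hit_genes = {
        id_map.get(h.transcript_id, h.transcript_id) if id_map else h.transcript_id
        for h in hits
    }
    return hit_genes & set(deg_ids)
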