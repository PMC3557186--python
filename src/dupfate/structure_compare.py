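"""Family-level gene-architecture comparison.

Locates regions missing in some family members (deletions/insertions relative
to a declared reference row of an alignment), classifies each event's reading-
frame effect, and groups events shared across taxa. This reproduces the
comparative-mapping view of a duplicated gene family: which paralogs lost
which cassettes, and whether those losses shift the coding frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aligner import GAP, MSA

Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class IndelEvent:
    """One insertion/deletion relative to the reference row.

    ``aln_interval`` is in alignment columns (1-based inclusive);
    ``ref_interval`` in ungapped reference positions. For insertions the
    reference span is empty and ``ref_interval = (p, p)`` where p is the last
    reference position before the inserted block (0 at the 5' end).
    """

    kind: str  # "insertion" | "deletion"
    aln_interval: Interval
    ref_interval: Interval
    length: int
    context: str  # "coding" | "noncoding"
    frame_effect: str  # "in-frame" | "frameshift" | "not-applicable"
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in {"insertion", "deletion"}:
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.kind == "deletion":
            # a deletion's length is its reference span; the alignment span
            # can be wider when another row's insertion interleaves
            width = self.ref_interval[1] - self.ref_interval[0] + 1
        else:
            width = self.aln_interval[1] - self.aln_interval[0] + 1
        if self.length != width:
            raise ValueError("IndelEvent: length inconsistent with interval width")


def classify_frame_effect(context: str, length: int) -> str:
    """in-frame iff the event is coding and a multiple of 3 bp long."""
    if context != "coding":
        return "not-applicable"
    return "in-frame" if length % 3 == 0 else "frameshift"


def map_indels(
    msa: MSA,
    reference_id: str,
    coding_mask: list[Interval] | None = None,
    include_terminal: bool = False,
) -> list[IndelEvent]:
    """Extract indel events from an MSA relative to one reference row.

    Maximal runs of gap columns in a non-reference row (where the reference
    has sequence) become deletions; maximal runs of gap columns in the
    reference (where a row has sequence) become insertions carried by that
    row. Events identical in kind and columns are merged into one event with
    multiple carriers. Terminal gap runs (unsequenced ends) are excluded
    unless ``include_terminal``.

    ``coding_mask`` gives coding intervals in 1-based inclusive *reference*
    coordinates; when omitted the whole sequence is treated as coding (the
    cDNA-alignment case).
    """
    ref = msa.row(reference_id)  # KeyError for unknown reference
    ncol = msa.n_cols
    # Reference position (1-based, ungapped) reached at or before each column.
    ref_pos = []
    p = 0
    for ch in ref:
        if ch != GAP:
            p += 1
        ref_pos.append(p)

    ref_seq = ref.replace(GAP, "")
    ref_first = _first_residue(ref)
    ref_last = _last_residue(ref)
    ref_cols = [i for i in range(ncol) if ref[i] != GAP]
    ref_gap_blocks = list(_gap_blocks(ref))
    merged: dict[tuple[str, Interval, Interval], set[str]] = {}
    for row_id, row in zip(msa.ids, msa.rows):
        if row_id == reference_id:
            continue
        first = _first_residue(row)
        last = _last_residue(row)
        for kind, start, end, length in _row_events(
            row, ref_cols, ref_gap_blocks
        ):
            if not include_terminal:
                # unsequenced 5'/3' ends are missing data, not indels
                if kind == "deletion" and (end < first or start > last):
                    continue
                if kind == "insertion" and (end < ref_first or start > ref_last):
                    continue
            # Canonicalize to the leftmost score-equivalent placement so
            # coordinates are reproducible across alignments.
            if kind == "deletion":
                re_pos = ref_pos[end]
                rs_pos = re_pos - length + 1
                s_norm = left_normalize_deletion(ref_seq, rs_pos, length)
                shift = rs_pos - s_norm
                key = (
                    kind,
                    (start + 1 - shift, end + 1 - shift),
                    (s_norm, s_norm + length - 1),
                )
            else:
                flank = ref_pos[start]  # residues before the inserted block
                p_norm, _ = left_normalize_insertion(
                    ref_seq, flank, row[start : end + 1].replace(GAP, "")
                )
                shift = flank - p_norm
                key = (
                    kind,
                    (start + 1 - shift, end + 1 - shift),
                    (p_norm, p_norm),
                )
            merged.setdefault(key, set()).add(row_id)

    events = []
    for (kind, (c1, c2), ref_iv), carriers in sorted(
        merged.items(), key=lambda kv: (kv[0][1], kv[0][0])
    ):
        if kind == "deletion":
            length = ref_iv[1] - ref_iv[0] + 1
        else:
            length = c2 - c1 + 1
        context = _context(ref_iv, kind, coding_mask)
        events.append(
            IndelEvent(
                kind=kind,
                aln_interval=(c1, c2),
                ref_interval=ref_iv,
                length=length,
                context=context,
                frame_effect=classify_frame_effect(context, length),
                carriers=frozenset(carriers),
            )
        )
    return events


def left_normalize_deletion(ref_seq: str, start: int, length: int) -> int:
    """Leftmost equivalent placement of a deletion (1-based start).

    Deleting ``ref_seq[start..start+length-1]`` is indistinguishable from the
    shifted deletion whenever the base before the window equals its last
    base; all stages canonicalize to the leftmost placement so planted and
    recovered coordinates agree exactly.
    """
    s = start
    while s > 1 and ref_seq[s - 2] == ref_seq[s + length - 2]:
        s -= 1
    return s


def left_normalize_insertion(ref_seq: str, flank: int, inserted: str) -> tuple[int, str]:
    """Leftmost equivalent placement of an insertion after reference
    position ``flank`` (0 = before the sequence). Returns (flank, inserted)."""
    p, ins = flank, inserted
    while p > 0 and ins and ins[-1] == ref_seq[p - 1]:
        ins = ref_seq[p - 1] + ins[:-1]
        p -= 1
    return p, ins


def _first_residue(row: str) -> int:
    for i, ch in enumerate(row):
        if ch != GAP:
            return i
    return len(row)


def _last_residue(row: str) -> int:
    for i in range(len(row) - 1, -1, -1):
        if row[i] != GAP:
            return i
    return -1


def _gap_blocks(ref: str):
    """Maximal runs of reference-gap columns, as (col_start, col_end)."""
    start = None
    for i, ch in enumerate(ref):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            yield start, i - 1
            start = None
    if start is not None:
        yield start, len(ref) - 1


def _row_events(row: str, ref_cols: list[int], ref_gap_blocks: list[Interval]):
    """Yield (kind, col_start, col_end, length) events for one row.

    Deletions are maximal row-gap runs *projected onto reference-bearing
    columns*, so another row's insertion interleaved in the alignment does
    not split a deletion; the length is the reference span. Insertions are
    the row's residues inside one reference-gap block (contiguous by
    construction of the alignments consumed here).
    """
    run: list[int] = []
    for c in ref_cols:
        if row[c] == GAP:
            run.append(c)
        elif run:
            yield "deletion", run[0], run[-1], len(run)
            run = []
    if run:
        yield "deletion", run[0], run[-1], len(run)
    for bs, be in ref_gap_blocks:
        res = [c for c in range(bs, be + 1) if row[c] != GAP]
        if res:
            yield "insertion", res[0], res[-1], len(res)


def _context(
    ref_iv: Interval, kind: str, coding_mask: list[Interval] | None
) -> str:
    if coding_mask is None:
        return "coding"
    if kind == "deletion":
        lo, hi = ref_iv
        lo = max(lo, 1)
        for s, e in coding_mask:
            if lo <= e and hi >= s:
                return "coding"
        return "noncoding"
    # insertion: coding if the insertion point lies strictly inside one
    # coding interval (both flanking reference positions coding).
    p = ref_iv[0]
    for s, e in coding_mask:
        if s <= p < e:
            return "coding"
    return "noncoding"


def shared_missing_regions(
    events: list[IndelEvent],
    min_carriers: int = 2,
    all_taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Group events by (kind, columns) and flag those shared by >= min_carriers.

    Returns one row per shared group with carriers and (when ``all_taxa`` is
    given) the taxa retaining the region.
    """
    rows = []
    for ev in events:
        if len(ev.carriers) < min_carriers:
            continue
        carriers = sorted(ev.carriers)
        non = (
            sorted(set(all_taxa) - ev.carriers) if all_taxa is not None else []
        )
        rows.append(
            {
                "kind": ev.kind,
                "aln_start": ev.aln_interval[0],
                "aln_end": ev.aln_interval[1],
                "ref_start": ev.ref_interval[0],
                "ref_end": ev.ref_interval[1],
                "length": ev.length,
                "context": ev.context,
                "frame_effect": ev.frame_effect,
                "n_carriers": len(carriers),
                "carriers": ",".join(carriers),
                "non_carriers": ",".join(non),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "aln_start", "aln_end", "ref_start", "ref_end", "length",
            "context", "frame_effect", "n_carriers", "carriers", "non_carriers",
        ],
    )


def indel_table(events: list[IndelEvent], reference_id: str) -> pd.DataFrame:
    """Flat TSV-ready event table; always names the reference."""
    rows = [
        {
            "kind": ev.kind,
            "aln_start": ev.aln_interval[0],
            "aln_end": ev.aln_interval[1],
            "ref_start": ev.ref_interval[0],
            "ref_end": ev.ref_interval[1],
            "length": ev.length,
            "context": ev.context,
            "frame_effect": ev.frame_effect,
            "carriers": ",".join(sorted(ev.carriers)),
            "reference": reference_id,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "aln_start", "aln_end", "ref_start", "ref_end", "length",
            "context", "frame_effect", "carriers", "reference",
        ],
    )
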