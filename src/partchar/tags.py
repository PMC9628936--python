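"""Barcode tag design, pairing and long-read demultiplexing.

Each picked colony is amplified with a forward and a reverse PCR primer
carrying a short (default 7 bp) barcode tag ahead of the primer binding
site.  Pooled reads are assigned back to colonies by locating the forward
tag near the read 5' end and the reverse-complemented reverse tag near the
3' end, within a small edit-distance budget.  Eight forward and twelve
reverse tags address a 96-colony plate; combined with 24 platform barcodes
the multiplexing capacity reaches 2304 samples per flow cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .parts import BASES, revcomp

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Tag:
    tag_id: str
    sequence: str
    orientation: str  # FORWARD or REVERSE

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if set(self.sequence) - set(BASES):
            raise ValueError(f"tag {self.tag_id}: non-ACGT sequence {self.sequence!r}")


@dataclass(frozen=True)
class TagPair:
    """A forward × reverse tag combination addressing one colony."""

    fwd: Tag
    rev: Tag
    colony_index: int

    def __post_init__(self) -> None:
        if self.fwd.orientation != FORWARD or self.rev.orientation != REVERSE:
            raise ValueError("TagPair requires a forward and a reverse tag, in that order")


@dataclass
class Assignment:
    """Where a read's tags were found; carries the trim window for genotyping."""

    read_id: str
    pair: TagPair
    orientation: str            # "+" if the read was already tag-first, "-" if flipped
    edit_distance: int          # summed over both tags
    trimmed_seq: str            # oriented read with both tags removed


@dataclass
class DemuxBin:
    pair: TagPair
    read_ids: list[str] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def seqlev(a: str, b: str) -> int:
    """Sequence-Levenshtein distance between two barcodes.

    The minimum over the last row and column of the Levenshtein DP matrix:
    the distance when either barcode may shed terminal bases into (or
    absorb bases from) the DNA context it is embedded in.  This is the
    right separation measure for barcodes read at the end of a longer
    molecule, where a deletion-damaged tag plus adjacent constant sequence
    can masquerade as a different tag under plain Levenshtein spacing.
    """
    return min(
        edlib.align(a, b, mode="SHW", task="distance")["editDistance"],
        edlib.align(b, a, mode="SHW", task="distance")["editDistance"],
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def packing_bound(length: int, min_dist: int) -> int:
    """Sphere-packing upper bound on a barcode set of given length/distance.

    Uses the Hamming ball volume at radius floor((d-1)/2); for Levenshtein
    sets this remains a (loose) upper bound on what greedy search can hope
    to reach and is used only to fail impossible requests fast.
    """
    radius = (min_dist - 1) // 2
    volume = sum(comb(length, i) * 3**i for i in range(radius + 1))
    return 4**length // volume


def design_tags(
    n_tags: int,
    length: int = 7,
    min_dist: int = 3,
    seed: int = 0,
    orientation: str = FORWARD,
    metric: str = "seqlev",
    max_homopolymer: int = 3,
    existing: list[str] | None = None,
    avoid_context: list[str] | None = None,
    avoid_k: int = 1,
    max_attempts: int | None = None,
) -> list[Tag]:
    """Greedy random search for a minimum-distance barcode set.

    Candidates are random k-mers filtered for homopolymer runs ≤ 3 and
    against self-complementarity, then accepted if at least `min_dist`
    edits away from every tag already in the set.  The default metric is
    sequence-Levenshtein (`"seqlev"`), the embedded-barcode distance under
    which edit-damaged tags at a read terminus stay decodable; plain
    `"levenshtein"` (indel-aware, context-free) and `"hamming"` are
    selectable.  Deterministic given `seed`.

    `existing` holds tag sequences the new set must also keep `min_dist`
    from — pass the forward set when designing the reverse set, so a tag
    read on the wrong strand can never be mistaken for the other
    orientation's tag.  `avoid_context` holds constant sequences every
    read carries (primer-binding sites and their neighbourhoods); a
    candidate is rejected when it occurs within `avoid_k` edits anywhere
    inside such a sequence or its reverse complement, which would make the
    context itself light up in every read's tag search (`avoid_k` should be
    at least the demultiplexer's edit budget).
    """
    if n_tags < 1:
        raise ValueError("n_tags must be >= 1")
    bound = packing_bound(length, min_dist)
    if n_tags > bound:
        raise ValueError(
            f"{n_tags} tags of length {length} at min_dist {min_dist} is infeasible: "
            f"sphere-packing bound is {bound}"
        )
    try:
        dist = {"seqlev": seqlev, "levenshtein": levenshtein, "hamming": hamming}[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = 20_000 + 2_000 * n_tags
    prefix = "F" if orientation == FORWARD else "R"
    others = list(existing or [])
    contexts = []
    for ctx in avoid_context or []:
        contexts.append(ctx.upper())
        contexts.append(revcomp(ctx.upper()))
    accepted: list[str] = []
    for _ in range(max_attempts):
        cand = "".join(rng.choice(list(BASES), size=length))
        if _max_homopolymer(cand) > max_homopolymer:
            continue
        if revcomp(cand) == cand:
            continue
        if any(dist(cand, t) < min_dist for t in accepted):
            continue
        if any(dist(cand, t) < min_dist for t in others):
            continue
        if contexts and any(
            edlib.align(cand, ctx, mode="HW", task="distance",
                        k=avoid_k)["editDistance"] != -1
            for ctx in contexts
        ):
            continue
        accepted.append(cand)
        if len(accepted) == n_tags:
            return [
                Tag(tag_id=f"{prefix}{i+1:02d}", sequence=s, orientation=orientation)
                for i, s in enumerate(accepted)
            ]
    raise ValueError(
        f"could not place {n_tags} tags of length {length} at min_dist {min_dist} "
        f"after {max_attempts} attempts; reached {len(accepted)}"
    )


def enumerate_pairs(fwd_tags: list[Tag], rev_tags: list[Tag]) -> list[TagPair]:
    """Cartesian product of forward × reverse tags, row-major colony index."""
    if not fwd_tags or not rev_tags:
        raise ValueError("tag lists must be non-empty")
    for tags, name in ((fwd_tags, "forward"), (rev_tags, "reverse")):
        seqs = [t.sequence for t in tags]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"duplicate sequences in {name} tag list")
    return [
        TagPair(fwd=f, rev=r, colony_index=i * len(rev_tags) + j)
        for i, f in enumerate(fwd_tags)
        for j, r in enumerate(rev_tags)
    ]


def multiplex_capacity(n_platform_barcodes: int, n_fwd: int, n_rev: int) -> int:
    """Samples addressable when tag pairs are nested inside platform barcodes."""
    return n_platform_barcodes * n_fwd * n_rev


def _best_tags(window: str, tags: list[Tag], queries: list[str], max_edit: int):
    """Tags whose query matches a prefix of `window` at minimal distance ≤ max_edit.

    Start-anchored (edlib SHW): the tag must begin at the window start with
    only its end free to shed into or borrow from the downstream sequence —
    the decoding that pairs with sequence-Levenshtein barcode spacing.
    Returns (best_distance, [(tag, match_end)]); empty list when nothing is
    within budget.
    """
    best = max_edit + 1
    hits: list[tuple[Tag, int]] = []
    for tag, query in zip(tags, queries):
        res = edlib.align(query, window, mode="SHW", task="locations", k=max_edit)
        d = res["editDistance"]
        if d == -1:
            continue
        if d < best:
            best = d
            hits = [(tag, res["locations"][0][1])]
        elif d == best:
            hits.append((tag, res["locations"][0][1]))
    return best, hits


def _demux_one_orientation(seq, fwd_tags, fwd_qs, rev_tags, rev_qs_reversed,
                           window, max_edit):
    head = seq[:window]
    tail_rev = seq[-window:][::-1]  # anchor the reverse tag at the read 3' end
    fd, fhits = _best_tags(head, fwd_tags, fwd_qs, max_edit)
    rd, rhits = _best_tags(tail_rev, rev_tags, rev_qs_reversed, max_edit)
    if not fhits:
        return ("no-fwd", None)
    if not rhits:
        return ("no-rev", None)
    if len(fhits) > 1 or len(rhits) > 1:
        return ("ambiguous", None)
    ftag, fend = fhits[0]
    rtag, rend = rhits[0]
    trim_start = fend + 1
    trim_end = len(seq) - (rend + 1)
    return ("ok", (ftag, rtag, fd + rd, seq[trim_start:trim_end]))


def demultiplex(
    reads,
    pairs: list[TagPair],
    max_edit: int = 1,
    search_window: int | None = None,
    binding_len: int = 18,
) -> tuple[list[DemuxBin], list[tuple[str, str]]]:
    """Assign pooled reads to colony tag pairs.

    `reads` is an iterable of ``(read_id, sequence)`` or Biopython
    SeqRecords.  Both strands of each read are searched: the forward tag in
    the first `search_window` bases, the reverse-complemented reverse tag in
    the last.  A read is assigned iff exactly one declared pair matches
    within `max_edit` at each end; every ambiguity (two tags tied at an end,
    the two strands supporting different pairs, a tag combination not in
    `pairs`) leaves the read unassigned with a reason — conservative
    demultiplexing never best-guesses.

    Tags sit at the read termini by construction, so the default window is
    just the tag length plus `max_edit` + 4 bases of indel jitter; widening
    it to cover the primer-binding site makes near-matches inside that
    constant sequence light up in every read and only breeds ambiguity.
    The binding site itself is skipped over (`binding_len`), never matched.

    Returns (bins — one per declared pair, empty ones included —,
    unassigned as (read_id, reason) tuples).
    """
    fwd_tags = sorted({p.fwd for p in pairs}, key=lambda t: t.tag_id)
    rev_tags = sorted({p.rev for p in pairs}, key=lambda t: t.tag_id)
    if not fwd_tags:
        raise ValueError("no tag pairs supplied")
    tag_len = len(fwd_tags[0].sequence)
    if search_window is None:
        search_window = tag_len + max_edit + 4
    if max_edit >= max(1, tag_len) and max_edit > 0:
        raise ValueError("max_edit must be smaller than the tag length")

    fwd_qs = [t.sequence for t in fwd_tags]
    # the tail carries revcomp(rev tag); reversed for end-anchored matching
    rev_qs = [revcomp(t.sequence)[::-1] for t in rev_tags]
    by_key = {(p.fwd.tag_id, p.rev.tag_id): p for p in pairs}
    bins = {(p.fwd.tag_id, p.rev.tag_id): DemuxBin(pair=p) for p in pairs}
    unassigned: list[tuple[str, str]] = []

    for read in reads:
        if hasattr(read, "id"):
            read_id, seq = read.id, str(read.seq).upper()
        else:
            read_id, seq = read[0], read[1].upper()
        candidates = []
        reasons = []
        for oriented, strand in ((seq, "+"), (revcomp(seq), "-")):
            status, hit = _demux_one_orientation(
                oriented, fwd_tags, fwd_qs, rev_tags, rev_qs, search_window, max_edit
            )
            if status == "ok":
                candidates.append((strand, hit))
            else:
                reasons.append(status)
        if not candidates:
            # prefer the more informative reason when the strands disagree
            reason = "ambiguous" if "ambiguous" in reasons else reasons[0]
            unassigned.append((read_id, reason))
            continue
        if len(candidates) == 2:
            candidates.sort(key=lambda c: c[1][2])  # lower total edit distance wins
            if candidates[0][1][2] == candidates[1][1][2] and (
                candidates[0][1][0].tag_id,
                candidates[0][1][1].tag_id,
            ) != (candidates[1][1][0].tag_id, candidates[1][1][1].tag_id):
                unassigned.append((read_id, "ambiguous"))
                continue
        strand, (ftag, rtag, dist, trimmed) = candidates[0]
        key = (ftag.tag_id, rtag.tag_id)
        if key not in by_key:
            unassigned.append((read_id, "unknown-pair"))
            continue
        pair = by_key[key]
        bins[key].read_ids.append(read_id)
        bins[key].assignments.append(
            Assignment(
                read_id=read_id,
                pair=pair,
                orientation=strand,
                edit_distance=dist,
                trimmed_seq=trimmed,
            )
        )
    return list(bins.values()), unassigned


def read_count_report(bins: list[DemuxBin]) -> pd.DataFrame:
    """Read counts as a forward × reverse grid (plate-layout semantics)."""
    fwd_ids = sorted({b.pair.fwd.tag_id for b in bins})
    rev_ids = sorted({b.pair.rev.tag_id for b in bins})
    table = pd.DataFrame(0, index=fwd_ids, columns=rev_ids, dtype=int)
    for b in bins:
        table.loc[b.pair.fwd.tag_id, b.pair.rev.tag_id] += b.n_reads
    table.index.name = "fwd_tag"
    table.columns.name = "rev_tag"
    return table


# -------------------------------------------------------------------- I/O

def write_tags_tsv(tags: list[Tag], path: str | Path) -> None:
    pd.DataFrame(
        [(t.tag_id, t.orientation, t.sequence) for t in tags],
        columns=["tag_id", "orientation", "sequence"],
    ).to_csv(path, sep="\t", index=False)


def read_tags_tsv(path: str | Path) -> list[Tag]:
    df = pd.read_csv(path, sep="\t")
    return [
        Tag(tag_id=row.tag_id, orientation=row.orientation, sequence=row.sequence)
        for row in df.itertuples()
    ]
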