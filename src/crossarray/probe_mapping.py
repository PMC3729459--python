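"""Probe-to-transcript matching and cross-platform probe-pair construction.

Probes are matched directly against transcript sequences by Hamming distance
(at most one mismatch by default), on both the given strand and the reverse
complement.  Probes hitting 100 or more locations across the catalog —
the signature of high-copy repeats — are discarded.  A 25-mer probeset is
assigned to a transcript only when strictly more than half of its probes
match that transcript; a 50-mer probe is assigned wherever it matches.  A
probe pair is one (probeset, probe) couple assigned to the same transcript:
per transcript the full cross product of its assigned probesets and probes,
so two probesets and two probes on one transcript yield four pairs.

Matching uses pigeonhole seeding: a probe with at most ``max_mismatch``
substitutions must contain at least one of ``max_mismatch + 1`` disjoint
exact k-mer chunks, so candidate placements are read off a k-mer index of
the catalog and verified by direct Hamming count.  Probes too short for
seeding fall back to a full window scan.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .exceptions import ConsistencyError, InvalidArgumentError, InvalidSequenceError
from .synthetic_data import ProbeRecord, TranscriptCatalog

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

SENSE = "sense"
REVCOMP = "revcomp"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(seq: str) -> None:
    if not seq or set(seq) - _VALID:
        raise InvalidSequenceError(f"sequence contains non-ACGT characters: {seq!r}")


@dataclass(frozen=True, order=True)
class ProbeMatch:
    probe_id: str
    transcript_id: str
    mismatches: int
    offset: int          # 0-based start on the transcript
    strand: str


def _hamming_at_most(a: str, b: str, limit: int) -> int:
    """Hamming distance between equal-length strings, or limit+1 if exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


class TranscriptIndex:
    """k-mer index over a catalog supporting mismatch-tolerant probe lookup."""

    def __init__(self, catalog: TranscriptCatalog, k: int = 12):
        if len(catalog) == 0:
            raise InvalidArgumentError("catalog is empty")
        if k < 4:
            raise InvalidArgumentError("seed length k must be >= 4")
        self.catalog = catalog
        self.k = k
        self._kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for t, entry in enumerate(catalog.entries):
            seq = entry.sequence
            for pos in range(len(seq) - k + 1):
                self._kmers[seq[pos : pos + k]].append((t, pos))

    def _candidates(self, seq: str, max_mismatch: int):
        """Candidate (transcript index, offset) placements via pigeonhole seeds."""
        k = self.k
        n_chunks = max_mismatch + 1
        out = set()
        for c in range(n_chunks):
            chunk_off = c * k
            chunk = seq[chunk_off : chunk_off + k]
            for t, pos in self._kmers.get(chunk, ()):
                start = pos - chunk_off
                if start >= 0:
                    out.add((t, start))
        return out

    def match(self, probe_sequence: str, max_mismatch: int = 1) -> list[ProbeMatch]:
        """All placements of the probe (either strand) within ``max_mismatch``.

        Each (transcript, offset) placement is reported once; if both strands
        fit, the strand with fewer mismatches wins (sense on ties).  Results
        are ordered by (transcript_id, offset).
        """
        probe_sequence = probe_sequence.upper()
        _validate_sequence(probe_sequence)
        if len(probe_sequence) < 10:
            raise InvalidArgumentError("probe length must be >= 10")
        L = len(probe_sequence)
        use_seeds = L >= (max_mismatch + 1) * self.k

        best: dict[tuple[int, int], tuple[int, str]] = {}
        for strand, seq in ((SENSE, probe_sequence), (REVCOMP, reverse_complement(probe_sequence))):
            if use_seeds:
                candidates = self._candidates(seq, max_mismatch)
            else:
                candidates = {
                    (t, start)
                    for t, entry in enumerate(self.catalog.entries)
                    for start in range(len(entry.sequence) - L + 1)
                }
            for t, start in candidates:
                tseq = self.catalog.entries[t].sequence
                if start + L > len(tseq):
                    continue
                d = _hamming_at_most(tseq[start : start + L], seq, max_mismatch)
                if d <= max_mismatch:
                    prev = best.get((t, start))
                    if prev is None or d < prev[0]:
                        best[(t, start)] = (d, strand)

        matches = [
            ProbeMatch(
                probe_id="",
                transcript_id=self.catalog.entries[t].transcript_id,
                mismatches=d,
                offset=start,
                strand=strand,
            )
            for (t, start), (d, strand) in best.items()
        ]
        matches.sort(key=lambda m: (m.transcript_id, m.offset))
        return matches


def match_probe(
    probe_sequence: str,
    catalog: TranscriptCatalog,
    max_mismatch: int = 1,
    index: TranscriptIndex | None = None,
) -> list[ProbeMatch]:
    """Match one probe sequence against a catalog (convenience wrapper).

    Builds a fresh index unless one is supplied; batch callers should build
    a :class:`TranscriptIndex` once and reuse it.
    """
    if index is None:
        index = TranscriptIndex(catalog)
    return index.match(probe_sequence, max_mismatch=max_mismatch)


def map_probes(
    probes: list[ProbeRecord],
    catalog: TranscriptCatalog,
    max_mismatch: int = 1,
    index: TranscriptIndex | None = None,
) -> dict[str, list[ProbeMatch]]:
    """Match every probe, returning probe_id -> placements (possibly empty)."""
    if index is None:
        index = TranscriptIndex(catalog)
    out: dict[str, list[ProbeMatch]] = {}
    for p in probes:
        hits = index.match(p.sequence, max_mismatch=max_mismatch)
        out[p.probe_id] = [
            ProbeMatch(p.probe_id, m.transcript_id, m.mismatches, m.offset, m.strand)
            for m in hits
        ]
    return out


def discard_promiscuous(
    matches_by_probe: dict[str, list[ProbeMatch]],
    location_threshold: int = 100,
) -> dict[str, list[ProbeMatch]]:
    """Drop probes whose total placement count reaches the threshold.

    The count is over all placements in the catalog, including multiple
    placements on one transcript; a probe at exactly the threshold is
    discarded (suspected high-copy repeat), one below it is kept.
    """
    if location_threshold < 1:
        raise InvalidArgumentError("location_threshold must be >= 1")
    kept = {}
    n_dropped = 0
    for pid, matches in matches_by_probe.items():
        if len(matches) >= location_threshold:
            n_dropped += 1
            logger.info(
                "probe %s discarded: %d locations >= threshold %d",
                pid, len(matches), location_threshold,
            )
        else:
            kept[pid] = matches
    if n_dropped:
        logger.info("discarded %d promiscuous probes", n_dropped)
    return kept


def map_probeset(
    probe_ids: list[str],
    matches_by_probe: dict[str, list[ProbeMatch]],
    transcript_id: str,
) -> bool:
    """Majority rule for probeset-to-transcript assignment.

    True iff strictly more than half of the probeset's probes have at least
    one placement on the transcript.  Probes absent from ``matches_by_probe``
    (e.g. discarded as promiscuous) count toward the denominator as
    non-matching.
    """
    if not probe_ids:
        raise InvalidArgumentError("probeset is empty")
    n_hit = sum(
        any(m.transcript_id == transcript_id for m in matches_by_probe.get(pid, ()))
        for pid in probe_ids
    )
    return n_hit > len(probe_ids) / 2.0


def assign_probesets(
    probes: list[ProbeRecord],
    matches_by_probe: dict[str, list[ProbeMatch]],
) -> dict[str, set[str]]:
    """transcript_id -> set of probeset ids passing the >50% majority rule.

    The majority is taken over the *original* probeset size: promiscuous
    probes removed upstream still count as non-matching members.
    """
    probeset_members: dict[str, list[str]] = defaultdict(list)
    for p in probes:
        probeset_members[p.probeset_id].append(p.probe_id)

    assignments: dict[str, set[str]] = defaultdict(set)
    for psid, members in probeset_members.items():
        candidates = {
            m.transcript_id
            for pid in members
            for m in matches_by_probe.get(pid, ())
        }
        for tid in candidates:
            if map_probeset(members, matches_by_probe, tid):
                assignments[tid].add(psid)
    return dict(assignments)


def assign_single_probes(
    matches_by_probe: dict[str, list[ProbeMatch]],
) -> dict[str, set[str]]:
    """transcript_id -> set of single-probe ids with >=1 surviving placement."""
    assignments: dict[str, set[str]] = defaultdict(set)
    for pid, matches in matches_by_probe.items():
        for m in matches:
            assignments[m.transcript_id].add(pid)
    return dict(assignments)


@dataclass
class ProbePairTable:
    """Cross-platform probe pairs: one row per (probeset, probe) couple mapped
    to a common transcript."""

    table: pd.DataFrame  # columns: affy_probeset_id, ilmn_probe_id, transcript_id, gene_symbol

    COLUMNS = ["affy_probeset_id", "ilmn_probe_id", "transcript_id", "gene_symbol"]

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise InvalidArgumentError(f"pair table missing columns {sorted(missing)}")
        if self.table.duplicated().any():
            raise ConsistencyError("duplicate probe-pair rows")

    @property
    def m(self) -> int:
        """Total number of probe pairs — the multiple-testing family size."""
        return len(self.table)

    @property
    def pair_ids(self) -> pd.Index:
        return pd.Index(
            self.table["affy_probeset_id"] + "::" + self.table["ilmn_probe_id"],
            name="pair_id",
        )

    def summary(self) -> dict:
        return {
            "m": self.m,
            "n_probesets": int(self.table["affy_probeset_id"].nunique()),
            "n_probes": int(self.table["ilmn_probe_id"].nunique()),
            "n_transcripts": int(self.table["transcript_id"].nunique()),
            "n_genes": int(self.table["gene_symbol"].nunique()),
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProbePairTable":
        return cls(pd.read_csv(path, sep="\t"))


def build_probe_pairs(
    affy_assignments: dict[str, set[str]],
    ilmn_assignments: dict[str, set[str]],
    catalog: TranscriptCatalog,
) -> ProbePairTable:
    """Cross product of assigned probesets and probes per shared transcript.

    The row count satisfies m = sum over transcripts of
    ``|probesets(t)| * |probes(t)|``.
    """
    gene_of = catalog.gene_of
    known = set(catalog.transcript_ids)
    for tid in set(affy_assignments) | set(ilmn_assignments):
        if tid not in known:
            raise ConsistencyError(f"assignment references unknown transcript {tid}")

    rows = []
    for tid in catalog.transcript_ids:  # catalog order for determinism
        probesets = sorted(affy_assignments.get(tid, ()))
        probes = sorted(ilmn_assignments.get(tid, ()))
        for psid in probesets:
            for pid in probes:
                rows.append((psid, pid, tid, gene_of[tid]))
    table = pd.DataFrame(rows, columns=ProbePairTable.COLUMNS)
    return ProbePairTable(table)


def map_platform_pairs(
    affy_probes: list[ProbeRecord],
    ilmn_probes: list[ProbeRecord],
    catalog: TranscriptCatalog,
    max_mismatch: int = 1,
    location_threshold: int = 100,
) -> ProbePairTable:
    """Full mapping pipeline: match both platforms' probes, drop promiscuous
    probes, apply the probeset majority rule, and build the pair table."""
    index = TranscriptIndex(catalog)
    affy_matches = discard_promiscuous(
        map_probes(affy_probes, catalog, max_mismatch, index), location_threshold
    )
    ilmn_matches = discard_promiscuous(
        map_probes(ilmn_probes, catalog, max_mismatch, index), location_threshold
    )
    affy_assign = assign_probesets(affy_probes, affy_matches)
    ilmn_assign = assign_single_probes(ilmn_matches)
    return build_probe_pairs(affy_assign, ilmn_assign, catalog)
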