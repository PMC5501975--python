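"""Canonical miRNA seed-match site detection and consensus voting.

A miRNA represses an mRNA through base-pairing between its *seed*
(nucleotides 2-8 counted from the miRNA 5' end) and a complementary
*site* in the mRNA 3'-UTR.  The canonical site taxonomy, ordered from
most to least stringent, is:

========  ======================================================  ======
type      definition (target 5'->3')                              length
========  ======================================================  ======
8mer      revcomp(miRNA 2-8) followed by A opposite position 1       8
7mer-m8   revcomp(miRNA 2-8)                                         7
7mer-A1   revcomp(miRNA 2-7) followed by A opposite position 1       7
6mer      revcomp(miRNA 2-7)                                         6
offset-   revcomp(miRNA 3-8)                                         6
6mer
6mer-A1   revcomp(miRNA 2-6) followed by A opposite position 1       6
========  ======================================================  ======

The A "opposite position 1" is an adenine in the target that boosts
efficacy regardless of the miRNA's first nucleotide, so it is matched
as a literal A, never as a complement.

Six stringency *modes* emulate a panel of independent target-prediction
programs; a gene's vote count is the number of modes that detect at
least one site (see :func:`consensus_votes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SITE_TYPES",
    "SITE_LENGTHS",
    "SeedSite",
    "ConsensusPrediction",
    "SequenceError",
    "site_sequence",
    "find_seed_sites",
    "find_gu_6mers",
    "consensus_votes",
]

#: site types ordered most- to least-stringent
SITE_TYPES: tuple[str, ...] = (
    "8mer",
    "7mer-m8",
    "7mer-A1",
    "6mer",
    "offset-6mer",
    "6mer-A1",
)

SITE_LENGTHS: dict[str, int] = {
    "8mer": 8,
    "7mer-m8": 7,
    "7mer-A1": 7,
    "6mer": 6,
    "offset-6mer": 6,
    "6mer-A1": 6,
}

#: miRNA positions paired by each site type (1-based, inclusive)
SITE_MIRNA_POSITIONS: dict[str, tuple[int, int]] = {
    "8mer": (2, 8),
    "7mer-m8": (2, 8),
    "7mer-A1": (2, 7),
    "6mer": (2, 7),
    "offset-6mer": (3, 8),
    "6mer-A1": (2, 6),
}

_STRINGENCY_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SequenceError(ValueError):
    """Raised for sequences with symbols outside {A, C, G, T, U}."""


def _normalize(seq: str, what: str) -> str:
    """Uppercase, map U->T, reject anything outside the alphabet."""
    if not seq:
        raise SequenceError(f"empty {what} sequence")
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in "ACGT":
            raise SequenceError(
                f"invalid symbol {seq[i]!r} at position {i + 1} of {what}"
            )
    return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class SeedSite:
    """One seed-match occurrence on a 3'-UTR.

    Coordinates are 1-based inclusive on the UTR read 5'->3'.
    ``matched_mirna_positions`` is the inclusive interval of miRNA
    nucleotides paired by the site (the trailing A of A1 types pairs
    nothing).  ``site_type`` "6mer-GU" marks a 6mer accepted with one
    G:U wobble; it only arises from :func:`find_gu_6mers`.
    """

    gene_id: str
    start: int
    end: int
    site_type: str
    matched_mirna_positions: tuple[int, int]

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        expected = SITE_LENGTHS.get(self.site_type, 6)
        if length != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got {length}"
            )


@dataclass
class ConsensusPrediction:
    """Vote count and per-mode site lists for one gene.

    ``votes`` plays the role of the "number of prediction programs"
    column in a consensus target list: each of the six stringency modes
    stands in for one predictor.
    """

    gene_id: str
    votes: int
    sites_by_mode: dict[int, list[SeedSite]] = field(default_factory=dict)


def site_sequence(mirna_sequence: str, site_type: str) -> str:
    """Target-strand (5'->3') sequence of a perfect site of ``site_type``."""
    m = _normalize(mirna_sequence, "miRNA")
    if len(m) < 8:
        raise SequenceError("miRNA must be at least 8 nt")
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site type {site_type!r}")
    lo, hi = SITE_MIRNA_POSITIONS[site_type]
    core = _revcomp(m[lo - 1 : hi])
    if site_type in ("8mer", "7mer-A1", "6mer-A1"):
        core += "A"
    return core


def find_seed_sites(
    utr_sequence: str,
    mirna_sequence: str,
    site_types: set[str] | tuple[str, ...] | None = None,
    gene_id: str = "",
) -> list[SeedSite]:
    """Locate every perfect seed-match occurrence in a UTR.

    Returns all occurrences of all requested site types, sorted by
    start position then descending stringency.  Overlapping and nested
    sites of different types are each reported.
    """
    utr = _normalize(utr_sequence, "UTR")
    requested = tuple(site_types) if site_types is not None else SITE_TYPES
    for t in requested:
        if t not in SITE_TYPES:
            raise ValueError(f"unknown site type {t!r}")
    hits: list[SeedSite] = []
    for t in requested:
        pattern = site_sequence(mirna_sequence, t)
        start = utr.find(pattern)
        while start != -1:
            hits.append(
                SeedSite(
                    gene_id=gene_id,
                    start=start + 1,
                    end=start + len(pattern),
                    site_type=t,
                    matched_mirna_positions=SITE_MIRNA_POSITIONS[t],
                )
            )
            start = utr.find(pattern, start + 1)
    hits.sort(key=lambda s: (s.start, _STRINGENCY_RANK[s.site_type]))
    return hits


def find_gu_6mers(
    utr_sequence: str,
    mirna_sequence: str,
    max_wobble: int = 1,
    gene_id: str = "",
) -> list[SeedSite]:
    """6mer matches to miRNA positions 2-7 allowing up to ``max_wobble``
    G:U wobble pairs (miRNA G opposite target T, or miRNA T opposite
    target G); every other pair must be Watson-Crick."""
    utr = _normalize(utr_sequence, "UTR")
    m = _normalize(mirna_sequence, "miRNA")
    if len(m) < 8:
        raise SequenceError("miRNA must be at least 8 nt")
    seed = m[1:7]  # positions 2-7
    hits: list[SeedSite] = []
    for start in range(len(utr) - 5):
        window = utr[start : start + 6]
        wobbles = 0
        ok = True
        # antiparallel: window base j pairs seed base (5 - j)
        for j in range(6):
            mb = seed[5 - j]
            tb = window[j]
            if tb == _COMPLEMENT[mb]:
                continue
            if (mb == "G" and tb == "T") or (mb == "T" and tb == "G"):
                wobbles += 1
                if wobbles > max_wobble:
                    ok = False
                    break
            else:
                ok = False
                break
        if ok:
            site_type = "6mer" if wobbles == 0 else "6mer-GU"
            hits.append(
                SeedSite(
                    gene_id=gene_id,
                    start=start + 1,
                    end=start + 6,
                    site_type=site_type,
                    matched_mirna_positions=(2, 7),
                )
            )
    return hits


def consensus_votes(
    utr_sequence: str, mirna_sequence: str, gene_id: str = ""
) -> ConsensusPrediction:
    """Emulated six-predictor consensus vote for one UTR.

    The modes, most to least stringent:

    1. 8mer only
    2. 8mer or 7mer-m8
    3. any of 8mer / 7mer-m8 / 7mer-A1
    4. any of the above or 6mer
    5. an offset-6mer match (miRNA positions 3-8; 8mer and 7mer-m8
       sites contain one, a plain 6mer does not)
    6. 6mer allowing one G:U wobble in the pairing

    ``votes`` counts the modes with >= 1 site.  Any site satisfying a
    stringent mode also satisfies every less stringent mode that
    subsumes it (e.g. an 8mer contains a 6mer), so votes grow
    monotonically with site quality.
    """
    sites = find_seed_sites(utr_sequence, mirna_sequence, gene_id=gene_id)
    by_type: dict[str, list[SeedSite]] = {t: [] for t in SITE_TYPES}
    for s in sites:
        by_type[s.site_type].append(s)

    mode_sets = [
        ("8mer",),
        ("8mer", "7mer-m8"),
        ("8mer", "7mer-m8", "7mer-A1"),
        ("8mer", "7mer-m8", "7mer-A1", "6mer"),
        ("offset-6mer",),
    ]
    sites_by_mode: dict[int, list[SeedSite]] = {}
    for k, types in enumerate(mode_sets, start=1):
        found = [s for t in types for s in by_type[t]]
        found.sort(key=lambda s: (s.start, _STRINGENCY_RANK[s.site_type]))
        sites_by_mode[k] = found
    sites_by_mode[6] = find_gu_6mers(
        utr_sequence, mirna_sequence, gene_id=gene_id
    )
    votes = sum(1 for k in range(1, 7) if sites_by_mode[k])
    return ConsensusPrediction(
        gene_id=gene_id, votes=votes, sites_by_mode=sites_by_mode
    )
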