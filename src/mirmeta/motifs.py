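"""Log-odds PWM scanning of promoter sequences with ATG-relative output.

A position weight matrix (PWM) gives a probability distribution over
{A, C, G, T} at each motif position; a window of sequence is scored as
sum(log2(p_motif(base) / p_background(base))) over positions.  Both
strands are scanned and hits are reported in coordinates counted from
the translational start: the base immediately 5' of the A of ATG is
-1, so a hit interval is written (upstream_edge, downstream_edge) with
upstream_edge < downstream_edge < 0, matching the "-4530/-4515"
notation used for promoter binding sites.  Only windows lying fully
upstream of the ATG are considered; windows containing N are skipped.

The default matrix is an E2F-like consensus TTTSSCGC expanded into a
PWM with probability 0.95 on the consensus base(s) at each position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Pwm", "MotifHit", "scan_pwm", "e2f_default_pwm", "read_jaspar_pwm"]

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class Pwm:
    """Position probability matrix plus background and hit threshold.

    ``threshold`` is interpreted per ``threshold_mode``: "logodds"
    takes it as an absolute log2-odds score; "fraction" (default) as a
    fraction in [0, 1] of the maximum attainable score.
    """

    name: str
    matrix: np.ndarray  # (length, 4) probabilities over ACGT
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float = 0.8
    threshold_mode: str = "fraction"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if self.background.shape != (4,) or not np.isclose(
            self.background.sum(), 1.0, atol=1e-9
        ):
            raise ValueError("background must be a distribution over ACGT")
        if self.threshold_mode not in ("fraction", "logodds"):
            raise ValueError("threshold_mode must be 'fraction' or 'logodds'")
        if self.threshold_mode == "fraction" and not (0.0 <= self.threshold <= 1.0):
            raise ValueError("fractional threshold must lie in [0, 1]")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def score_cutoff(self) -> float:
        if self.threshold_mode == "logodds":
            return float(self.threshold)
        return float(self.threshold * self.max_score)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        name: str = "",
        match_prob: float = 0.95,
        **kwargs,
    ) -> "Pwm":
        """Expand an IUPAC consensus into a PWM.

        At each position the consensus base(s) share ``match_prob`` of
        the probability mass; the remaining bases share the rest.
        """
        rows = []
        for ch in consensus.upper():
            allowed = _IUPAC.get(ch)
            if allowed is None:
                raise ValueError(f"invalid IUPAC symbol {ch!r}")
            row = np.empty(4)
            n_in = len(allowed)
            if n_in == 4:
                row[:] = 0.25
            else:
                row[:] = (1.0 - match_prob) / (4 - n_in)
                for b in allowed:
                    row[_INDEX[b]] = match_prob / n_in
            rows.append(row)
        return cls(name=name or consensus, matrix=np.array(rows), **kwargs)


def e2f_default_pwm(**kwargs) -> Pwm:
    """Default E2F-family PWM built from the TTTSSCGC consensus."""
    return Pwm.from_consensus("TTTSSCGC", name="E2F", **kwargs)


def read_jaspar_pwm(path, pseudocount: float = 0.5, **kwargs) -> Pwm:
    """Read the first motif of a JASPAR-format matrix file as a Pwm.

    Counts are converted to probabilities with ``pseudocount`` added
    per cell.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in _ALPHABET], dtype=float).T
    counts += pseudocount
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return Pwm(name=motif.name or motif.matrix_id or "jaspar", matrix=matrix, **kwargs)


@dataclass(frozen=True)
class MotifHit:
    """One PWM hit upstream of the ATG.

    ``upstream_edge`` / ``downstream_edge`` are ATG-relative positions
    (-1 = base immediately 5' of the A of ATG), both negative, closed
    interval.  ``strand`` is '+' or '-'; the interval always refers to
    the forward strand of the given sequence.
    """

    upstream_edge: int
    downstream_edge: int
    strand: str
    score: float


def _window_scores(window: str, lo: np.ndarray) -> tuple[float, float]:
    """Forward- and reverse-strand log-odds scores of one window."""
    fwd = 0.0
    rev = 0.0
    length = len(window)
    for i, base in enumerate(window):
        bi = _INDEX[base]
        fwd += lo[i, bi]
        rev += lo[length - 1 - i, 3 - bi]  # complement index: A<->T, C<->G
    return fwd, rev


def scan_pwm(sequence: str, atg_position: int, pwm: Pwm) -> list[MotifHit]:
    """Scan the region upstream of the ATG for PWM hits on both strands.

    Parameters
    ----------
    sequence : promoter sequence over {A, C, G, T, N}, 5'->3'.
    atg_position : 1-based index of the A of the ATG in ``sequence``.
    pwm : matrix, background and threshold.

    Returns hits with score >= the PWM's cutoff, sorted most-upstream
    first (ties: '+' strand before '-').  Windows containing N and
    windows overlapping or downstream of the ATG are skipped.
    """
    seq = sequence.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid symbol {sequence[i]!r} at position {i + 1}")
    if not (1 <= atg_position <= len(seq)):
        raise ValueError(
            f"atg_position {atg_position} outside sequence of length {len(seq)}"
        )
    lo = pwm.log_odds
    length = len(pwm)
    cutoff = pwm.score_cutoff
    hits: list[MotifHit] = []
    # windows [p, p + length - 1] fully 5' of the ATG (1-based p)
    for p in range(1, atg_position - length + 1):
        window = seq[p - 1 : p - 1 + length]
        if "N" in window:
            continue
        fwd, rev = _window_scores(window, lo)
        up = p - atg_position
        down = p + length - 1 - atg_position
        if fwd >= cutoff:
            hits.append(MotifHit(up, down, "+", float(fwd)))
        if rev >= cutoff:
            hits.append(MotifHit(up, down, "-", float(rev)))
    hits.sort(key=lambda h: (h.upstream_edge, h.strand))
    return hits
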