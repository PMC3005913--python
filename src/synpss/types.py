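"""Shared domain types: protein chains and local pairwise alignments.

Coordinates are 0-based half-open internally; every file format and every
user-facing report uses 1-based inclusive positions. The conversion happens
exactly once, at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SS_STATES = "HEC"


@dataclass(frozen=True)
class ProteinChain:
    """A protein chain, optionally with its three-state secondary structure.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    sequence : str
        Amino-acid sequence over the 20 standard letters plus X.
    ss3 : str, optional
        Per-residue structure string over {H, E, C}, same length as
        ``sequence``. Present for template/pool proteins, absent for
        prediction targets.
    """

    id: str
    sequence: str
    ss3: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"chain {self.id!r}: empty sequence")
        if self.ss3 is not None:
            if len(self.ss3) != len(self.sequence):
                raise ValueError(
                    f"chain {self.id!r}: ss3 length {len(self.ss3)} != "
                    f"sequence length {len(self.sequence)}"
                )
            bad = set(self.ss3) - set(SS_STATES)
            if bad:
                raise ValueError(
                    f"chain {self.id!r}: ss3 contains non-HEC states {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocalAlignment:
    """A gapped local alignment segment pair, BLAST HSP style.

    ``query_start`` / ``subject_start`` are 1-based positions of the first
    aligned residue on the ungapped query/subject sequences. The two aligned
    rows have equal length and no column is a gap in both rows.
    """

    query_id: str
    subject_id: str
    query_start: int
    subject_start: int
    query_aln: str
    subject_aln: str
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.subject_aln):
            raise ValueError(
                f"alignment {self.query_id}/{self.subject_id}: row lengths differ "
                f"({len(self.query_aln)} vs {len(self.subject_aln)})"
            )
        if self.query_start < 1 or self.subject_start < 1:
            raise ValueError("alignment start positions are 1-based (>= 1)")
        for q, s in zip(self.query_aln, self.subject_aln):
            if q == "-" and s == "-":
                raise ValueError(
                    f"alignment {self.query_id}/{self.subject_id}: "
                    "column gapped in both rows"
                )

    @property
    def query_segment(self) -> str:
        """The ungapped query subsequence covered by this alignment."""
        return self.query_aln.replace("-", "")

    @property
    def subject_segment(self) -> str:
        return self.subject_aln.replace("-", "")

    def check_against(self, query: ProteinChain) -> None:
        """Verify the query row against the actual query sequence.

        Raises ``ValueError`` if the ungapped query row does not reproduce
        the query subsequence starting at ``query_start``.
        """
        seg = self.query_segment
        start0 = self.query_start - 1
        actual = query.sequence[start0 : start0 + len(seg)]
        if actual != seg:
            raise ValueError(
                f"alignment {self.query_id}/{self.subject_id}: query row "
                f"disagrees with sequence of {query.id!r} at position "
                f"{self.query_start}"
            )


@dataclass
class PredictorConfig:
    """Run configuration for dictionary building and prediction.

    ``word_length`` defaults to 8 with inexact (one don't-care) matching,
    the combination found optimal for this approach; 7 is the recommended
    word length for exact matching. ``evalue_threshold`` filters parsed
    alignments; the search parameters are recorded as provenance only.
    """

    word_length: int = 8
    matching: str = "inexact"  # "exact" or "inexact"
    evalue_threshold: float = 1e-3
    # provenance of the similarity search that produced the alignments
    search_params: dict = field(
        default_factory=lambda: {"j": 3, "b": 500, "e": 1e-3}
    )

    def __post_init__(self) -> None:
        if self.matching not in ("exact", "inexact"):
            raise ValueError(f"matching must be exact|inexact, got {self.matching!r}")
        if self.word_length < 2:
            raise ValueError("word_length must be >= 2")
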