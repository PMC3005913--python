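"""Substitution matrices.

The BLOSUM62 table is embedded verbatim (NCBI distribution) so that word
similarity levels never drift with an external dependency's matrix revision.
Two residues are *interchangeable* when their BLOSUM62 score is strictly
positive; the number of interchangeable positions in an aligned word pair is
its similarity level.
"""

from __future__ import annotations

# NCBI BLOSUM62, half-bit scores. Rows/columns over the 20 standard residues
# plus B, Z, X and the stop character. Ambiguous letters are retained in the
# table but words containing them are skipped upstream.
_BLOSUM62_TEXT = """\
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  B  Z  X  *
A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0 -2 -1  0 -4
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3 -1  0 -1 -4
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3  3  0 -1 -4
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3  4  1 -1 -4
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1 -3 -3 -2 -4
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2  0  3 -1 -4
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2  1  4 -1 -4
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3 -1 -2 -1 -4
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3  0  0 -1 -4
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3 -3 -3 -1 -4
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1 -4 -3 -1 -4
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2  0  1 -1 -4
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1 -3 -1 -1 -4
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1 -3 -3 -1 -4
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2 -2 -1 -2 -4
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2  0  0  0 -4
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0 -1 -1  0 -4
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3 -4 -3 -2 -4
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1 -3 -2 -1 -4
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4 -3 -2 -1 -4
B -2 -1  3  4 -3  0  1 -1  0 -3 -4  0 -3 -3 -2  0 -1 -4 -3 -3  4  1 -1 -4
Z -1  0  0  1 -3  3  4 -2  0 -3 -3  1 -1 -3 -1  0 -1 -3 -2 -2  1  4 -1 -4
X  0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1 -1 -1 -1 -4
* -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4  1
"""


def _parse(text: str) -> dict[tuple[str, str], int]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    cols = lines[0].split()
    table: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for col, score in zip(cols, parts[1:]):
            table[(row, col)] = int(score)
    return table


#: BLOSUM62 scores keyed by ordered residue pair; symmetric.
BLOSUM62: dict[tuple[str, str], int] = _parse(_BLOSUM62_TEXT)

#: The 20 standard amino-acid letters.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letters excluded from word extraction: positivity under BLOSUM62 is
#: undefined (X, U, O) or ambiguous (B, Z).
NONWORD_LETTERS: frozenset[str] = frozenset("BZXUO*")


def blosum62(a: str, b: str) -> int:
    """Return the BLOSUM62 score for an aligned residue pair."""
    try:
        return BLOSUM62[(a, b)]
    except KeyError:
        raise KeyError(f"no BLOSUM62 score for pair {a!r}/{b!r}") from None


def is_word(word: str) -> bool:
    """True if every letter is a standard residue (word usable for matching)."""
    return all(c not in NONWORD_LETTERS for c in word) and all(
        c in STANDARD_AA for c in word
    )
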