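"""Synthetic template pools and homolog alignments.

Emulates the shape of a similarity search's output — local pairwise
alignments between a protein and its similar proteins at 25-100% identity,
with BLOSUM62-plausible substitutions and short indels — so that dictionary
building, prediction, calibration and shared-word alignment can all be
exercised offline, with a ground-truth alignment for every generated
homolog.

What is emulated: segment-structured three-state assignments (helices and
strands come in runs, never isolated single residues), state-conditional
residue propensities, substitutions preferring positive-BLOSUM62 partners,
and geometric-length indels. What is not: e-value statistics, profile
iteration, compositional bias, or any real protein family structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import STANDARD_AA, blosum62
from .types import LocalAlignment, ProteinChain

# Robinson-Robinson style background frequencies over the 20 standard
# residues (order of STANDARD_AA).
_BACKGROUND = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.091,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}

# Mild state-conditional propensity multipliers (Chou-Fasman flavoured):
# helix formers in H, beta-branched/aromatic in E, breakers in C.
_PROPENSITY = {
    "H": {"A": 1.4, "E": 1.5, "L": 1.3, "M": 1.3, "Q": 1.3, "K": 1.2,
          "P": 0.4, "G": 0.5},
    "E": {"V": 1.7, "I": 1.6, "Y": 1.4, "F": 1.3, "W": 1.3, "T": 1.2,
          "P": 0.4, "G": 0.7},
    "C": {"P": 1.5, "G": 1.5, "N": 1.3, "S": 1.2, "D": 1.2},
}


@dataclass
class HomologSimConfig:
    """Conditions for one synthetic pool.

    Identity range mirrors what a similarity search reports for true hits
    (25-100%); hits per protein is capped at 500, matching the customary
    report limit. Structure segments follow a three-state renewal model
    with per-state mean/minimum lengths so that SOV is meaningful.
    """

    seed: int = 0
    n_templates: int = 30
    length_range: tuple[int, int] = (80, 160)
    identity_range: tuple[float, float] = (0.25, 1.0)
    hits_per_protein: int = 10
    indel_rate: float = 0.02
    mean_indel_length: float = 2.0
    max_indel_length: int = 4
    ss_mean_lengths: dict = field(
        default_factory=lambda: {"H": 10.0, "E": 5.0, "C": 6.0}
    )
    ss_min_lengths: dict = field(default_factory=lambda: {"H": 3, "E": 2, "C": 1})
    ss_state_weights: dict = field(
        default_factory=lambda: {"H": 0.35, "E": 0.25, "C": 0.40}
    )

    def __post_init__(self) -> None:
        lo, hi = self.identity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("identity range must lie within (0, 1]")
        if self.hits_per_protein > 500:
            raise ValueError("hits_per_protein capped at 500")
        if lo == hi == 1.0 and self.indel_rate > 0:
            raise ValueError(
                "identity 1.0 with a nonzero indel rate is infeasible"
            )


def sample_ss3(length: int, config: HomologSimConfig, rng: np.random.Generator) -> str:
    """Draw a segment-structured three-state string."""
    states = list("HEC")
    weights = np.array([config.ss_state_weights[s] for s in states], float)
    weights /= weights.sum()
    out: list[str] = []
    prev = None
    while len(out) < length:
        if prev is None:
            state = rng.choice(states, p=weights)
        else:
            w = weights.copy()
            w[states.index(prev)] = 0.0
            w /= w.sum()
            state = rng.choice(states, p=w)
        mean = config.ss_mean_lengths[state]
        lo = config.ss_min_lengths[state]
        seg = lo + rng.geometric(1.0 / max(mean - lo + 1, 1.0)) - 1
        out.extend(state * int(seg))
        prev = state
    return "".join(out[:length])


def _residue_probs(state: str) -> np.ndarray:
    probs = np.array([_BACKGROUND[a] for a in STANDARD_AA], float)
    mult = _PROPENSITY.get(state, {})
    for i, a in enumerate(STANDARD_AA):
        probs[i] *= mult.get(a, 1.0)
    return probs / probs.sum()


_STATE_PROBS = {s: _residue_probs(s) for s in "HEC"}
_AA = np.array(list(STANDARD_AA))


def sample_sequence(ss3: str, rng: np.random.Generator) -> str:
    """Draw residues conditional on the per-position structure state."""
    return "".join(
        _AA[rng.choice(len(_AA), p=_STATE_PROBS[s])] for s in ss3
    )


# substitution kernels: for each residue, weights over partners b != a,
# Boltzmann in the half-bit BLOSUM62 score, so positive partners dominate
def _subst_kernel(a: str) -> np.ndarray:
    w = np.array(
        [0.0 if b == a else 2.0 ** blosum62(a, b) for b in STANDARD_AA], float
    )
    return w / w.sum()


_SUBST = {a: _subst_kernel(a) for a in STANDARD_AA}


def substitute(a: str, rng: np.random.Generator) -> str:
    """Draw a non-identical partner preferring positive-BLOSUM62 pairs."""
    return str(_AA[rng.choice(len(_AA), p=_SUBST[a])])


def mutate_homolog(
    chain: ProteinChain,
    identity: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    mean_indel_length: float = 2.0,
    max_indel_length: int = 4,
    mutant_id: str | None = None,
) -> tuple[ProteinChain, LocalAlignment]:
    """Derive a homolog at the given identity, with its true alignment.

    Exactly round(identity * L) of the template positions stay identical;
    the rest are substituted with BLOSUM62-preferring partners. Indels
    open at rate ``indel_rate`` per position with geometric lengths
    (capped), inserting background residues or deleting template residues.
    The returned alignment has the template as query; identity 1.0 with no
    indels returns an exact copy and an all-match alignment.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    L = len(chain)
    n_ident = int(round(identity * L))
    ident_mask = np.zeros(L, dtype=bool)
    ident_mask[rng.choice(L, size=n_ident, replace=False)] = True

    qrow: list[str] = []
    srow: list[str] = []
    i = 0
    while i < L:
        if indel_rate > 0 and 0 < i < L - 1 and rng.random() < indel_rate:
            d = min(int(rng.geometric(1.0 / mean_indel_length)), max_indel_length)
            if rng.random() < 0.5:
                # insertion in the homolog: gap columns in the query row
                for _ in range(d):
                    qrow.append("-")
                    srow.append(str(_AA[rng.choice(len(_AA))]))
            else:
                # deletion in the homolog: gap in the subject row
                d = min(d, L - 1 - i)
                for k in range(d):
                    qrow.append(chain.sequence[i + k])
                    srow.append("-")
                i += d
                continue
        a = chain.sequence[i]
        qrow.append(a)
        srow.append(a if ident_mask[i] else substitute(a, rng))
        i += 1

    subject_seq = "".join(c for c in srow if c != "-")
    mid = mutant_id or f"{chain.id}_hom"
    mutant = ProteinChain(mid, subject_seq)
    aln = LocalAlignment(
        query_id=chain.id,
        subject_id=mid,
        query_start=1,
        subject_start=1,
        query_aln="".join(qrow),
        subject_aln="".join(srow),
        evalue=1e-10,
    )
    return mutant, aln


def generate_pool(
    config: HomologSimConfig,
) -> tuple[list[ProteinChain], dict[str, list[LocalAlignment]]]:
    """Generate a template pool with per-template homolog alignments.

    Reproducible for a fixed seed: templates carry segment-structured
    assignments, each with ``hits_per_protein`` homologs at identities
    drawn uniformly from the configured range. Returns the chains (with
    ss3) and the alignments keyed by template id.
    """
    rng = np.random.default_rng(config.seed)
    templates: list[ProteinChain] = []
    alignments: dict[str, list[LocalAlignment]] = {}
    lo, hi = config.length_range
    for i in range(config.n_templates):
        length = int(rng.integers(lo, hi + 1))
        ss3 = sample_ss3(length, config, rng)
        seq = sample_sequence(ss3, rng)
        tid = f"T{i:04d}"
        chain = ProteinChain(tid, seq, ss3)
        templates.append(chain)
        hits = []
        for j in range(config.hits_per_protein):
            ident = float(rng.uniform(*config.identity_range))
            _, aln = mutate_homolog(
                chain,
                ident,
                rng,
                indel_rate=config.indel_rate,
                mean_indel_length=config.mean_indel_length,
                max_indel_length=config.max_indel_length,
                mutant_id=f"{tid}_h{j:03d}",
            )
            hits.append(aln)
        alignments[tid] = hits
    return templates, alignments


@dataclass
class FamilyPoolConfig:
    """A pool organised into homologous families.

    Members of one family are derived from a common founder at the
    within-family identity and conserve the founder's structure; each
    member gets its own gapless full-length homolog hits. Families emulate
    the remote-homology structure of a real template pool: a held-out
    member can only be predicted through its relatives' synonymous words,
    never through its own.
    """

    seed: int = 0
    n_families: int = 10
    members_per_family: int = 3
    length_range: tuple[int, int] = (90, 140)
    within_family_identity: float = 0.55
    hits_per_protein: int = 10
    hit_identity_range: tuple[float, float] = (0.5, 0.9)

    def __post_init__(self) -> None:
        lo, hi = self.hit_identity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("hit identity range must lie within (0, 1]")
        if not 0.0 < self.within_family_identity <= 1.0:
            raise ValueError("within-family identity must lie within (0, 1]")


def generate_family_pool(
    config: FamilyPoolConfig,
) -> tuple[list[ProteinChain], dict[str, list[LocalAlignment]]]:
    """Generate a family-structured pool with per-member homolog hits.

    Returns n_families * members_per_family chains (ids ``F<f>M<m>``) and
    simple full-length gapless alignments keyed by member id.
    """
    rng = np.random.default_rng(config.seed)
    base = HomologSimConfig(seed=config.seed)
    chains: list[ProteinChain] = []
    alignments: dict[str, list[LocalAlignment]] = {}
    lo, hi = config.length_range
    for f in range(config.n_families):
        length = int(rng.integers(lo, hi + 1))
        ss3 = sample_ss3(length, base, rng)
        founder = ProteinChain(f"F{f:03d}", sample_sequence(ss3, rng), ss3)
        for m in range(config.members_per_family):
            mid = f"F{f:03d}M{m}"
            if m == 0:
                member = ProteinChain(mid, founder.sequence, ss3)
            else:
                mut, _ = mutate_homolog(
                    founder, config.within_family_identity, rng, mutant_id=mid
                )
                member = ProteinChain(mid, mut.sequence, ss3)
            chains.append(member)
            hits = []
            for h in range(config.hits_per_protein):
                ident = float(rng.uniform(*config.hit_identity_range))
                hmut, _ = mutate_homolog(
                    member, ident, rng, mutant_id=f"{mid}_h{h:03d}"
                )
                hits.append(
                    LocalAlignment(
                        query_id=mid,
                        subject_id=hmut.id,
                        query_start=1,
                        subject_start=1,
                        query_aln=member.sequence,
                        subject_aln=hmut.sequence,
                        evalue=1e-9,
                    )
                )
            alignments[mid] = hits
    return chains, alignments


def realized_identity(aln: LocalAlignment) -> float:
    """Fraction of identical residues among columns aligned in both rows."""
    pairs = [
        (q, s)
        for q, s in zip(aln.query_aln, aln.subject_aln)
        if q != "-" and s != "-"
    ]
    if not pairs:
        return 0.0
    return sum(1 for q, s in pairs if q == s) / len(pairs)
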