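"""Synthetic barcode communities and amplicon reads with ground truth.

Emulates a validation community of ~20 cloned protein-coding barcode
sequences (cpn60-style, ~550 bp) whose pairwise nucleotide identities span a
configured envelope (default 60-96%), including one maximally-similar pair
that differs only by synonymous substitutions so its peptides are identical.
Reads are drawn from the 5' or 3' end of the amplicon, with primers attached
before errors are applied, optional PCR chimeras, and a per-read truth label.

Community construction: one random ancestor coding sequence; each member is
the ancestor with a per-member dose of point substitutions (stop codons
avoided); the top pair is built by third-position synonymous changes only and
the bottom pair by two independent heavy substitution doses.  A calibration
loop measures realized global-alignment identities and adds/reverts
substitutions until the configured envelope bounds are attained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._align import global_aligner, revcomp
from .io import Read

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
# codon prefixes whose third position is fourfold degenerate
_FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# generic degenerate amplification primers (synthetic stand-ins, not a
# published primer pair)
DEFAULT_FWD_PRIMER = "TGGYAARGAAGGYGTNATYAC"
DEFAULT_REV_PRIMER = "RCCRCCCATRCCACCCATYTT"


class ConstraintError(ValueError):
    """The requested community constraints are infeasible."""


@dataclass
class CommunityTemplate:
    """A synthetic community: members, true proportions, identity structure."""

    members: list[tuple[str, str]]
    proportions: np.ndarray
    identity_matrix: np.ndarray
    synonymous_pair: tuple[str, str] | None = None

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0):
            raise ValueError("negative proportion")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        for name, seq in self.members:
            if len(seq) % 3 != 0:
                raise ValueError(f"member {name}: length not divisible by 3")
            for i in range(0, len(seq) - 2, 3):
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(f"member {name}: internal stop codon at {i}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.members]

    def seq(self, name: str) -> str:
        for n, s in self.members:
            if n == name:
                return s
        raise KeyError(name)


@dataclass
class ReadSimConfig:
    """Amplicon read simulation parameters (per library)."""

    n_reads: int = 5000
    read_length_mean: float = 400.0
    read_length_sd: float = 40.0
    frac_5prime: float = 0.5
    sub_rate: float = 0.005
    indel_rate: float = 0.0
    chimera_rate: float = 0.0
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    min_read_length: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_5prime", "sub_rate", "indel_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


@dataclass
class CommunityTruth:
    """Simulator ground truth: per-read sources and true composition."""

    community: CommunityTemplate
    read_sources: dict[str, str] = field(default_factory=dict)
    member_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def true_proportions(self, library: str | None = None) -> dict[str, float]:
        """Realized (multinomial-draw) member proportions among non-chimeric reads."""
        if library is None:
            totals: dict[str, int] = {}
            for counts in self.member_counts.values():
                for m, c in counts.items():
                    totals[m] = totals.get(m, 0) + c
        else:
            totals = dict(self.member_counts[library])
        n = sum(totals.values())
        return {m: c / n for m, c in totals.items()} if n else {}


_GLOBAL = global_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from an optimal global alignment.

    Scoring: match +1, mismatch -1, gap -2 (linear).  Identity is
    matches / alignment columns x 100, counting every column of the global
    alignment.  Symmetric by construction (arguments are ordered internally).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    x, y = (a, b) if a <= b else (b, a)
    aln = _GLOBAL.align(x, y)[0]
    matches = aln.counts().identities
    return 100.0 * matches / aln.shape[1]


def _random_coding(rng: np.random.Generator, n_codons: int) -> list[str]:
    """Random coding sequence as a flat list of bases (no frame-0 stops)."""
    sense = sorted(set(a + b + c for a in BASES for b in BASES for c in BASES)
                   - STOP_CODONS)
    return list("".join(rng.choice(sense, size=n_codons)))


def _apply_substitutions(seq: list[str], positions, rng: np.random.Generator
                         ) -> None:
    """Mutate seq (list of chars) in place at positions, never creating a
    frame-0 stop codon."""
    for pos in positions:
        codon_start = (pos // 3) * 3
        current = seq[pos]
        choices = [b for b in BASES if b != current]
        rng.shuffle(choices)
        for b in choices:
            codon = seq[codon_start:codon_start + 3]
            codon[pos - codon_start] = b
            if "".join(codon) not in STOP_CODONS:
                seq[pos] = b
                break


def _divergent_copy(ancestor: list[str], frac: float, rng: np.random.Generator
                    ) -> list[str]:
    seq = list(ancestor)
    k = int(round(frac * len(seq)))
    positions = rng.choice(len(seq), size=k, replace=False)
    _apply_substitutions(seq, sorted(positions), rng)
    return seq


def _synonymous_twin(seq: list[str], n_changes: int, rng: np.random.Generator
                     ) -> list[str]:
    """Copy of seq with exactly n_changes third-position synonymous changes."""
    fourfold = [i for i in range(0, len(seq) - 2, 3)
                if "".join(seq[i:i + 2]) in _FOURFOLD_PREFIXES]
    if len(fourfold) < n_changes:
        raise ConstraintError(
            f"not enough fourfold-degenerate codons ({len(fourfold)}) for "
            f"{n_changes} synonymous changes")
    twin = list(seq)
    sites = rng.choice(len(fourfold), size=n_changes, replace=False)
    for s in sorted(sites):
        pos = fourfold[s] + 2
        alts = [b for b in BASES if b != twin[pos]]
        twin[pos] = alts[rng.integers(len(alts))]
    return twin


def generate_community(n: int, length_nt: int = 552,
                       identity_min: float = 60.0, identity_max: float = 96.0,
                       synonymous_pair: bool = True, seed: int = 0,
                       proportion_ratio: float = 0.9) -> CommunityTemplate:
    """Generate n coding barcode sequences spanning an identity envelope.

    At least one pair attains identity_max and (for n >= 3) one pair attains
    identity_min, each within +-1 percentage point; if synonymous_pair, the
    maximum-identity pair differs only by synonymous third-position changes
    so its frame-0 peptides are identical.  Deterministic under seed.
    """
    if n < 2:
        raise ConstraintError("n must be >= 2")
    if not (0 < identity_min <= identity_max <= 100):
        raise ConstraintError(
            f"need 0 < identity_min <= identity_max <= 100, "
            f"got [{identity_min}, {identity_max}]")
    if length_nt % 3 != 0 or length_nt < 30:
        raise ConstraintError("length_nt must be >= 30 and divisible by 3")
    if identity_max >= 100 and not synonymous_pair:
        raise ConstraintError(
            "identity_max=100 with distinct members requires synonymous_pair")

    rng = np.random.default_rng(seed)
    L = length_nt
    ancestor = _random_coding(rng, L // 3)

    # --- maximum-identity pair -------------------------------------------
    d0 = 0.03 if n > 2 else 0.0
    member_a = _divergent_copy(ancestor, d0, rng)
    k_max = max(1, int(round((1.0 - identity_max / 100.0) * L)))
    if synonymous_pair:
        member_b = _synonymous_twin(member_a, k_max, rng)
    else:
        member_b = list(member_a)
        positions = rng.choice(L, size=k_max, replace=False)
        _apply_substitutions(member_b, sorted(positions), rng)
    seqs = [member_a, member_b]

    # --- minimum-identity pair and mid-range members ----------------------
    m = identity_min / 100.0
    # identity of two independent doses a: (1-a)^2 + a^2/3 = m
    disc = 4.0 - (16.0 / 3.0) * (1.0 - m)
    if disc < 0:
        raise ConstraintError(f"identity_min {identity_min} unattainable")
    a_min = (2.0 - math.sqrt(disc)) / (8.0 / 3.0)
    if n >= 4:
        n_mid = n - 4
        mid_hi = max(0.05, 0.7 * a_min)
        mids = np.linspace(0.05, mid_hi, n_mid) if n_mid else []
        for d in mids:
            seqs.append(_divergent_copy(ancestor, float(d), rng))
        seqs.append(_divergent_copy(ancestor, a_min, rng))
        seqs.append(_divergent_copy(ancestor, a_min, rng))
        min_pair = (n - 2, n - 1)
    elif n == 3:
        # pair member_a (dose d0) with one heavy member
        a3 = (1.0 - d0 - m) / (1.0 - (4.0 / 3.0) * d0)
        if not 0 < a3 < 0.75:
            raise ConstraintError(f"identity_min {identity_min} unattainable")
        seqs.append(_divergent_copy(ancestor, a3, rng))
        min_pair = (0, 2)
    else:
        min_pair = None

    # --- calibrate the designated extreme pairs ---------------------------
    def _calibrate(i: int, j: int, target: float, synonymous: bool) -> None:
        for _ in range(80):
            realized = pairwise_identity("".join(seqs[i]), "".join(seqs[j]))
            if abs(realized - target) <= 0.5:
                return
            delta = max(1, int(round(abs(realized - target) / 100.0 * L)))
            if realized > target:  # add substitutions to j
                if synonymous:
                    extra = _synonymous_twin(seqs[j], delta, rng)
                    seqs[j] = extra
                else:
                    diverged = [p for p in range(L) if seqs[j][p] == ancestor[p]]
                    take = rng.choice(len(diverged), size=min(delta, len(diverged)),
                                      replace=False)
                    _apply_substitutions(seqs[j], sorted(diverged[t] for t in take),
                                         rng)
            else:  # revert substitutions in j toward i's sequence
                diffs = [p for p in range(L) if seqs[j][p] != seqs[i][p]]
                if len(diffs) <= delta:
                    delta = max(0, len(diffs) - 1)
                    if delta == 0:
                        return
                take = sorted(rng.choice(len(diffs), size=delta, replace=False))
                for t in take:
                    p = diffs[t]
                    codon_start = (p // 3) * 3
                    trial = list(seqs[j])
                    trial[p] = seqs[i][p]
                    if "".join(trial[codon_start:codon_start + 3]) not in STOP_CODONS:
                        seqs[j] = trial
        raise ConstraintError(
            f"could not calibrate pair ({i},{j}) to {target}%")

    _calibrate(0, 1, identity_max, synonymous_pair)
    if min_pair is not None:
        _calibrate(min_pair[0], min_pair[1], identity_min, synonymous=False)

    def _matrix() -> np.ndarray:
        m_ = np.full((n, n), 100.0)
        strs = ["".join(s) for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                m_[i, j] = m_[j, i] = pairwise_identity(strs[i], strs[j])
        return m_

    # --- repair non-designated pairs that drifted out of the envelope ------
    protected = {(0, 1)} | ({min_pair} if min_pair else set())
    for _ in range(40):
        ident = _matrix()
        worst = None  # (severity, i, j, direction)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in protected:
                    continue
                if ident[i, j] < identity_min - 0.5:
                    sev = identity_min - ident[i, j]
                    if worst is None or sev > worst[0]:
                        worst = (sev, i, j, "raise")
                elif ident[i, j] > identity_max + 0.5:
                    sev = ident[i, j] - identity_max
                    if worst is None or sev > worst[0]:
                        worst = (sev, i, j, "lower")
        if worst is None:
            break
        _, i, j, direction = worst
        delta = max(1, int(round(worst[0] / 100.0 * L)))
        if direction == "raise":  # pull j toward i
            diffs = [p for p in range(L) if seqs[j][p] != seqs[i][p]]
            take = rng.choice(len(diffs), size=min(delta, len(diffs)),
                              replace=False)
            for t in sorted(take):
                p = diffs[t]
                cs = (p // 3) * 3
                trial = list(seqs[j])
                trial[p] = seqs[i][p]
                if "".join(trial[cs:cs + 3]) not in STOP_CODONS:
                    seqs[j] = trial
        else:  # push j away from i
            same = [p for p in range(L) if seqs[j][p] == seqs[i][p]]
            take = rng.choice(len(same), size=min(delta, len(same)),
                              replace=False)
            _apply_substitutions(seqs[j], sorted(same[t] for t in take), rng)
        # repairs can perturb the designated extremes: re-pin them
        _calibrate(0, 1, identity_max, synonymous_pair)
        if min_pair is not None:
            _calibrate(min_pair[0], min_pair[1], identity_min,
                       synonymous=False)

    # --- assemble template, verify envelope --------------------------------
    width = max(2, len(str(n)))
    names = [f"member_{i + 1:0{width}d}" for i in range(n)]
    member_strs = ["".join(s) for s in seqs]
    if len(set(member_strs)) != n:
        raise ConstraintError("degenerate community: duplicate members")

    ident = _matrix()
    off_diag = ident[~np.eye(n, dtype=bool)]
    if off_diag.max() > identity_max + 1.0 or off_diag.min() < identity_min - 1.0:
        raise ConstraintError(
            f"realized identity envelope [{off_diag.min():.1f}, "
            f"{off_diag.max():.1f}] violates configured "
            f"[{identity_min}, {identity_max}]")

    # --- proportions: geometric series; twin pair at mid ranks -------------
    p = proportion_ratio ** np.arange(n)
    p /= p.sum()
    ranks = _rank_permutation(n)
    proportions = p[ranks]

    return CommunityTemplate(
        members=list(zip(names, member_strs)),
        proportions=proportions,
        identity_matrix=ident,
        synonymous_pair=(names[0], names[1]) if synonymous_pair else None,
    )


def _rank_permutation(n: int) -> np.ndarray:
    """Abundance rank per member index (0 = most abundant).

    The high-identity twin pair (indices 0 and 1) is placed at the 9th and
    11th abundance ranks when the community is large enough, mirroring a
    community in which the two most similar members have similar,
    mid-range abundances.
    """
    ranks = np.empty(n, dtype=int)
    if n >= 12:
        ranks[0], ranks[1] = 8, 10
        pool = [r for r in range(n) if r not in (8, 10)]
    else:
        ranks[0], ranks[1] = n - 2, n - 1
        pool = list(range(n - 2))
    for i, r in zip(range(2, n), pool):
        ranks[i] = r
    return ranks


def _resolve_degenerate(primer: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT" else IUPAC[c][rng.integers(len(IUPAC[c]))]
                   for c in primer)


def _mutate_read(seq: str, config: ReadSimConfig, rng: np.random.Generator
                 ) -> str:
    arr = list(seq)
    if config.sub_rate > 0:
        hits = np.nonzero(rng.random(len(arr)) < config.sub_rate)[0]
        for p in hits:
            alts = [b for b in BASES if b != arr[p]]
            arr[p] = alts[rng.integers(3)]
    if config.indel_rate > 0:
        out = []
        for c in arr:
            r = rng.random()
            if r < config.indel_rate / 2:
                continue  # deletion
            out.append(c)
            if config.indel_rate / 2 <= r < config.indel_rate:
                out.append(BASES[rng.integers(4)])  # insertion
        arr = out if out else arr
    return "".join(arr)


def simulate_reads(community: CommunityTemplate, config: ReadSimConfig,
                   libraries: list[str]) -> tuple[list[Read], CommunityTruth]:
    """Simulate per-library amplicon reads with truth labels.

    Reads are drawn from the 5' end (forward primer + template prefix) or
    the 3' end (reverse primer + reverse-complemented template suffix);
    chimeric reads join a prefix of one member to the suffix of another at a
    uniform breakpoint in [0.25L, 0.75L].  Errors are applied after primer
    attachment.  Deterministic under config.seed.
    """
    rng = np.random.default_rng(config.seed)
    names = community.names
    min_member_len = min(len(s) for _, s in community.members)
    if config.read_length_mean > min_member_len:
        raise ValueError(
            f"read_length_mean {config.read_length_mean} exceeds shortest "
            f"member length {min_member_len}")

    truth = CommunityTruth(community=community)
    reads: list[Read] = []
    for lib in libraries:
        n_chim = rng.binomial(config.n_reads, config.chimera_rate)
        counts = rng.multinomial(config.n_reads - n_chim, community.proportions)
        truth.member_counts[lib] = {nm: int(c) for nm, c in zip(names, counts)}
        sources: list[str] = []
        for nm, c in zip(names, counts):
            sources.extend([nm] * int(c))
        for _ in range(n_chim):
            i, j = rng.choice(len(names), size=2, replace=False,
                              p=community.proportions)
            sources.append(f"chimera:{names[i]}+{names[j]}")
        rng.shuffle(sources)

        for idx, src in enumerate(sources):
            if src.startswith("chimera:"):
                a, b = src[len("chimera:"):].split("+")
                sa, sb = community.seq(a), community.seq(b)
                lo = int(0.25 * len(sa))
                hi = int(0.75 * len(sa))
                bp = int(rng.integers(lo, hi + 1))
                template = sa[:bp] + sb[bp:]
            else:
                template = community.seq(src)
            length = int(np.clip(round(rng.normal(config.read_length_mean,
                                                  config.read_length_sd)),
                                 config.min_read_length, len(template)))
            if rng.random() < config.frac_5prime:
                raw = _resolve_degenerate(config.fwd_primer, rng) + template[:length]
            else:
                raw = (_resolve_degenerate(config.rev_primer, rng)
                       + revcomp(template[-length:]))
            seq = _mutate_read(raw, config, rng)
            rid = f"{lib}_r{idx + 1:06d}"
            reads.append(Read(id=rid, seq=seq, qual=[40] * len(seq),
                              library=lib, truth_source=src))
            truth.read_sources[rid] = src
    return reads, truth


def write_truth_tsv(truth: CommunityTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tsource\n")
        for rid, src in truth.read_sources.items():
            fh.write(f"{rid}\t{src}\n")
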