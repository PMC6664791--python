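"""Secondary-structure features: folding engines, sequence-structure
triplets, dinucleotide-preserving shuffles, and the Q_MFE permutation
statistic.

Q_MFE compares a sequence's predicted minimum free energy (PMFE) against
the PMFE distribution of N dinucleotide-preserving randomizations:

    Q_MFE = n / (N + 1)

where n counts randomized sequences whose PMFE is less than or equal to
the original. Low values mean more structure than expected by chance.

Folding is a pluggable contract. Three engines are provided:

* :class:`BaselineEngine` — an internal maximum-score nested-pairing
  folder (minimum hairpin loop 3) usable offline; its energies are a
  coarse stand-in, not thermodynamic values.
* :class:`ExternalEngine` — a subprocess adapter parsing RNAfold-style
  (``structure (-1.20)``) or UNAfold-style output.
* :class:`StubEngine` — a lookup table for unit tests.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from .errors import DegenerateInputError, EngineError
from .kmer import BASES, FeatureVector
from .sequence_io import RNA_ALPHABET, RnaSequence

# canonical + wobble pairs
_PAIRS: Mapping[frozenset, float] = {
    frozenset("GC"): 3.0,
    frozenset("AU"): 2.0,
    frozenset("GU"): 1.0,
}
MIN_HAIRPIN_LOOP = 3  # unpaired bases enclosed by a closing pair


def pair_score(a: str, b: str) -> float:
    """Stand-in stability score of pairing bases a:b (0 if unpairable)."""
    return _PAIRS.get(frozenset((a, b)), 0.0)


@dataclass(frozen=True)
class FoldResult:
    """Dot-bracket structure plus predicted MFE for one sequence."""

    structure: str
    pmfe: float
    engine: str = ""

    def __post_init__(self):
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket structure")
            elif ch != ".":
                raise ValueError(f"invalid structure character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket structure")

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@runtime_checkable
class FoldingEngine(Protocol):
    """Deterministic mapping from an RNA sequence to a FoldResult."""

    name: str

    def fold(self, seq: RnaSequence) -> FoldResult: ...


class StubEngine:
    """Unit-test engine answering from a preloaded table keyed by residues."""

    name = "stub"

    def __init__(self, table: Mapping[str, tuple[str, float]]):
        self._table = dict(table)

    def fold(self, seq: RnaSequence) -> FoldResult:
        try:
            structure, pmfe = self._table[seq.residues]
        except KeyError:
            raise EngineError(f"stub engine has no entry for {seq.id!r}")
        return FoldResult(structure, pmfe, engine=self.name)


class BaselineEngine:
    """Maximum-score nested pairing via dynamic programming.

    Maximizes the sum of per-pair scores (GC=3, AU=2, GU=1) over all
    pseudoknot-free structures with hairpin loops of at least
    ``MIN_HAIRPIN_LOOP`` unpaired bases. PMFE is minus the optimal score,
    so more paired sequences score lower; 0 when nothing can pair.
    Deterministic: ties resolve to the leftmost pairing partner.
    """

    name = "baseline"

    def fold(self, seq: RnaSequence) -> FoldResult:
        s = seq.residues
        if not RNA_ALPHABET.issuperset(s):
            raise EngineError(
                f"baseline engine requires pure ACGU input ({seq.id!r})"
            )
        n = len(s)
        if n == 0:
            raise DegenerateInputError("cannot fold empty sequence")
        E = np.zeros((n + 1, n + 1))
        # E[i][j]: best score on s[i..j] inclusive, 0-based
        for span in range(MIN_HAIRPIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = E[i][j - 1]  # j unpaired
                for k in range(i, j - MIN_HAIRPIN_LOOP):
                    sc = pair_score(s[k], s[j])
                    if sc <= 0:
                        continue
                    left = E[i][k - 1] if k > i else 0.0
                    cand = left + E[k + 1][j - 1] + sc
                    if cand > best:
                        best = cand
                E[i][j] = best
        structure = ["."] * n
        self._traceback(s, E, 0, n - 1, structure)
        score = E[0][n - 1] if n > 1 else 0.0
        return FoldResult("".join(structure), -float(score), engine=self.name)

    def _traceback(self, s, E, i, j, structure):
        while j - i > MIN_HAIRPIN_LOOP:
            if E[i][j] == E[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                sc = pair_score(s[k], s[j])
                if sc <= 0:
                    continue
                left = E[i][k - 1] if k > i else 0.0
                if E[i][j] == left + E[k + 1][j - 1] + sc:
                    structure[k] = "("
                    structure[j] = ")"
                    self._traceback(s, E, k + 1, j - 1, structure)
                    j = k - 1
                    break
            else:  # pragma: no cover - defensive
                raise EngineError("baseline traceback failed")


_RNAFOLD_LINE = re.compile(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


class ExternalEngine:
    """Adapter over an installed thermodynamic folder such as RNAfold.

    Parses the conventional ``<dot-bracket> (<energy>)`` output line; a
    structure-free energy of exactly 0 with no pairs is passed through.
    """

    def __init__(self, command: str = "RNAfold", extra_args: tuple[str, ...] = ("--noPS",)):
        self.command = command
        self.extra_args = extra_args
        self.name = f"external:{command}"

    def available(self) -> bool:
        return shutil.which(self.command) is not None

    def fold(self, seq: RnaSequence) -> FoldResult:
        if not self.available():
            raise EngineError(f"folding command not found: {self.command!r}")
        proc = subprocess.run(
            [self.command, *self.extra_args],
            input=f">{seq.id}\n{seq.residues}\n",
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise EngineError(
                f"{self.command} exited with status {proc.returncode}",
                raw_output=proc.stderr,
            )
        for line in proc.stdout.splitlines():
            m = _RNAFOLD_LINE.match(line.strip())
            if m and len(m.group(1)) == seq.length:
                return FoldResult(m.group(1), float(m.group(2)), engine=self.name)
        raise EngineError(
            f"could not parse {self.command} output", raw_output=proc.stdout
        )


def get_engine(name: str) -> FoldingEngine:
    """Engine factory for CLI use: ``baseline`` or ``external[:cmd]``."""
    if name == "baseline":
        return BaselineEngine()
    if name == "external":
        return ExternalEngine()
    if name.startswith("external:"):
        return ExternalEngine(command=name.split(":", 1)[1])
    raise ValueError(f"unknown folding engine {name!r}")


def fold(seq: RnaSequence, engine: FoldingEngine) -> FoldResult:
    """Fold a sequence, validating the engine's output invariants."""
    result = engine.fold(seq)
    if len(result.structure) != seq.length:
        raise EngineError(
            f"engine {engine.name!r} returned structure of length "
            f"{len(result.structure)} for sequence of length {seq.length}"
        )
    return result


# ---------------------------------------------------------------------------
# Triplet features
# ---------------------------------------------------------------------------

TRIPLET_STATES = ("(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...")


def triplet_names() -> list[str]:
    """The 32 triplet feature names: central base + 3 pairing states."""
    return [b + st for b in BASES for st in TRIPLET_STATES]


def triplet_features(seq: RnaSequence, fold_result: FoldResult) -> FeatureVector:
    """Joint base/pairing-state triplet frequencies.

    Each position is reduced to paired ``(`` or unpaired ``.`` (closing
    brackets map to ``(``). For every center position 2..L-1 the state
    triple of (i-1, i, i+1) plus the central base is one observation;
    counts are divided by the number of centers (L-2) so entries sum to 1.
    """
    if seq.length < 3:
        raise DegenerateInputError("triplet features need length >= 3")
    if len(fold_result.structure) != seq.length:
        raise ValueError("structure not aligned to sequence")
    states = fold_result.structure.replace(")", "(")
    names = triplet_names()
    index = {name: i for i, name in enumerate(names)}
    values = np.zeros(len(names))
    for center in range(1, seq.length - 1):
        key = seq.residues[center] + states[center - 1 : center + 2]
        if key in index:  # skip centers on ambiguity characters
            values[index[key]] += 1
    values /= seq.length - 2
    return FeatureVector(tuple(names), values)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving Euler shuffle
# ---------------------------------------------------------------------------


def _dinucleotide_edges(s: str) -> dict[str, list[str]]:
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    return edges


def dinucleotide_shuffle(
    seq: RnaSequence, rng: np.random.Generator | int
) -> RnaSequence:
    """Randomize a sequence preserving its exact dinucleotide composition.

    Walks a random Eulerian path on the dinucleotide transition multigraph
    (Altschul-Erikson): for every vertex other than the final residue a
    random last-exit edge is drawn until those edges form paths into the
    final vertex; remaining edges are shuffled per vertex and the walk is
    read off. First and last residues are preserved by construction.
    """
    if seq.length < 2:
        raise DegenerateInputError("shuffle needs length >= 2")
    if not RNA_ALPHABET.issuperset(seq.residues):
        raise ValueError("cannot shuffle sequences with ambiguity characters")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    s = seq.residues
    first, last = s[0], s[-1]
    edges = _dinucleotide_edges(s)
    vertices = list(edges)

    # draw last-exit edges until they form a functional graph whose every
    # vertex reaches `last`
    while True:
        last_exit = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != last
        }
        if all(_reaches(v, last, last_exit) for v in last_exit):
            break

    remaining: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = list(outs)
        if v != last:
            outs.remove(last_exit[v])
        rng.shuffle(outs)
        if v != last:
            outs.append(last_exit[v])
        remaining[v] = outs

    walk = [first]
    cursors = {v: 0 for v in remaining}
    v = first
    for _ in range(len(s) - 1):
        nxt = remaining[v][cursors[v]]
        cursors[v] += 1
        walk.append(nxt)
        v = nxt
    return RnaSequence(seq.id, "".join(walk))


def _reaches(v: str, target: str, last_exit: dict[str, str]) -> bool:
    seen = set()
    while v != target:
        if v in seen or v not in last_exit:
            return False
        seen.add(v)
        v = last_exit[v]
    return True


# ---------------------------------------------------------------------------
# Q_MFE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QmfeResult:
    """Summary of the permutation null: Q_MFE = n / (N + 1)."""

    pmfe_original: float
    N: int
    n: int
    engine: str = ""

    def __post_init__(self):
        if not (0 <= self.n <= self.N):
            raise ValueError("require 0 <= n <= N")

    @property
    def qmfe(self) -> float:
        return self.n / (self.N + 1)


def qmfe(
    seq: RnaSequence,
    N: int,
    engine: FoldingEngine,
    rng_seed: int | np.random.Generator = 0,
) -> QmfeResult:
    """Permutation statistic of structural stability.

    Folds the original sequence and N independent dinucleotide-preserving
    shuffles; n counts shuffles with PMFE <= the original (ties count, and
    PMFE comparison is exact on engine-reported values). Engine failure on
    any shuffle propagates — N is exact, never silently reduced.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    original = fold(seq, engine)
    n = 0
    for _ in range(N):
        shuffled = dinucleotide_shuffle(seq, rng)
        if fold(shuffled, engine).pmfe <= original.pmfe:
            n += 1
    return QmfeResult(original.pmfe, N, n, engine=engine.name)


QMFE_FEATURE_NAME = "QMFE"


def structural_feature_vector(
    seq: RnaSequence,
    engine: FoldingEngine,
    N: int = 2000,
    rng_seed: int | np.random.Generator = 0,
) -> FeatureVector:
    """32 triplet features plus Q_MFE: the 33-entry structural vector."""
    fold_result = fold(seq, engine)
    triplets = triplet_features(seq, fold_result)
    q = qmfe(seq, N, engine, rng_seed)
    return FeatureVector.concat(
        triplets,
        FeatureVector((QMFE_FEATURE_NAME,), np.array([q.qmfe])),
    )
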