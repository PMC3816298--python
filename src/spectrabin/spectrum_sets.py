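"""Spectrum sets: permutation classes of restriction-site base compositions.

A *spectrum set* is the collection of all distinct, non-palindromic words
obtained by permuting the base multiset of a length-6 bacterial restriction
site. Because known length-6 recognition sites are (DNA-)palindromic, their
compositions are self-complementary (nA == nT and nC == nG), and exactly four
such compositions exist at length 6. Each set is named after a canonical seed
word: AAATTT, AATTCG, CCGGAT and CCCGGG, with 12, 156, 156 and 12
non-palindromic members respectively. Palindromes are excluded from the sets
because restriction sites tend to be avoided in genomes, which would bias
coverage statistics.

A fifth profile space, ``PAL6``, is the exhaustive list of all 64 length-6
DNA palindromes; it is used for whole-chromosome relatedness trees rather
than for binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product
from typing import Iterator, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
ALPHABET = frozenset("ACGT")

#: Canonical seed words of the four non-palindromic spectrum sets.
SEED_NAMES: tuple[str, ...] = ("AAATTT", "AATTCG", "CCGGAT", "CCCGGG")

#: Name of the exhaustive length-6 palindrome profile space.
PALINDROME_SET_NAME = "PAL6"

#: All registered profile-space names.
SET_NAMES: tuple[str, ...] = SEED_NAMES + (PALINDROME_SET_NAME,)

_SEED_BY_COMPOSITION: Mapping[tuple[int, int, int, int], str] = {
    (3, 0, 0, 3): "AAATTT",
    (2, 1, 1, 2): "AATTCG",
    (1, 2, 2, 1): "CCGGAT",
    (0, 3, 3, 0): "CCCGGG",
}


def _validate_motif(motif: str) -> str:
    """Uppercase *motif* and reject empty or non-ACGT input."""
    if not motif:
        raise ValueError("motif must be a non-empty string")
    text = motif.upper()
    bad = set(text) - ALPHABET
    if bad:
        raise ValueError(
            f"motif {motif!r} contains non-ACGT characters: {sorted(bad)}"
        )
    return text


def reverse_complement(motif: str) -> str:
    """Return the reverse complement of a DNA word.

    An involution: ``reverse_complement(reverse_complement(m)) == m``.
    """
    return _validate_motif(motif).translate(_COMPLEMENT)[::-1]


def is_palindrome(motif: str) -> bool:
    """True iff the word equals its own reverse complement.

    This is the DNA-palindrome definition (``w == reversed(complemented(w))``),
    so e.g. GAATTC and ATGCAT are palindromic while ATTTAA is not. Odd-length
    words are never palindromic (the central base would have to equal its own
    complement).
    """
    text = _validate_motif(motif)
    return text == text.translate(_COMPLEMENT)[::-1]


def composition_of(motif: str) -> tuple[int, int, int, int]:
    """Base composition of a word as counts ``(nA, nC, nG, nT)``."""
    text = _validate_motif(motif)
    return (text.count("A"), text.count("C"), text.count("G"), text.count("T"))


def seed_for(composition: Sequence[int]) -> Optional[str]:
    """Map a length-6 base composition to its spectrum-set seed name.

    Returns ``None`` when the composition is not self-complementary
    (nA != nT or nC != nG), i.e. no spectrum set covers it.

    Raises
    ------
    ValueError
        If the composition is not a 4-tuple of non-negative ints summing to 6
        (only length 6 is registered).
    """
    comp = tuple(int(c) for c in composition)
    if len(comp) != 4 or any(c < 0 for c in comp):
        raise ValueError(f"composition must be 4 non-negative counts, got {composition!r}")
    if sum(comp) != 6:
        raise ValueError(
            f"only length-6 compositions are supported, got total {sum(comp)}"
        )
    return _SEED_BY_COMPOSITION.get(comp)


@dataclass(frozen=True)
class SpectrumSet:
    """An ordered, duplicate-free collection of motifs sharing one profile space.

    ``motifs`` is lexicographically sorted so that profile-matrix columns have
    a deterministic order. ``composition`` is the shared base composition for
    the four seed sets and ``None`` for PAL6 (whose members span all four
    self-complementary compositions).
    """

    name: str
    motifs: tuple[str, ...]
    composition: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError("spectrum set contains duplicate motifs")
        if list(self.motifs) != sorted(self.motifs):
            raise ValueError("spectrum set motifs must be lexicographically sorted")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.motifs)

    def __contains__(self, motif: object) -> bool:
        return motif in self.motifs


@lru_cache(maxsize=None)
def enumerate_spectrum_set(seed_name: str) -> SpectrumSet:
    """Enumerate the spectrum set of one of the four canonical seeds.

    All distinct permutations of the seed's base multiset are generated and
    palindromes removed; e.g. AAATTT has 6!/(3!3!) = 20 distinct arrangements
    of which 8 are palindromic, leaving 12 members.
    """
    if seed_name not in SEED_NAMES:
        raise ValueError(
            f"unknown seed {seed_name!r}; expected one of {', '.join(SEED_NAMES)}"
        )
    words = sorted({"".join(p) for p in permutations(seed_name)})
    members = tuple(w for w in words if not is_palindrome(w))
    return SpectrumSet(
        name=seed_name, motifs=members, composition=composition_of(seed_name)
    )


def enumerate_palindromes(length: int = 6) -> SpectrumSet:
    """All DNA palindromes of the given even length, sorted.

    A palindrome is fully determined by its first ``length/2`` bases, so there
    are ``4**(length/2)`` of them — 64 at length 6.
    """
    if length < 2 or length % 2:
        raise ValueError(f"palindrome length must be a positive even integer, got {length}")
    half = length // 2
    words = []
    for bases in product("ACGT", repeat=half):
        prefix = "".join(bases)
        words.append(prefix + prefix.translate(_COMPLEMENT)[::-1])
    name = PALINDROME_SET_NAME if length == 6 else f"PAL{length}"
    return SpectrumSet(name=name, motifs=tuple(sorted(words)))


def get_set(name: str) -> SpectrumSet:
    """Look up a registered profile space by name (four seeds or PAL6)."""
    if name in SEED_NAMES:
        return enumerate_spectrum_set(name)
    if name == PALINDROME_SET_NAME:
        return enumerate_palindromes(6)
    raise ValueError(f"unknown set name {name!r}; expected one of {', '.join(SET_NAMES)}")


def classify_sites(sites: Sequence[str]) -> dict[str, Optional[str]]:
    """Assign user-supplied length-6 recognition sites to spectrum sets.

    Sites whose composition is not self-complementary belong to no set; they
    are mapped to ``None`` and a warning is logged (every known length-6
    bacterial recognition site is expected to fit one of the four sets).
    """
    out: dict[str, Optional[str]] = {}
    for site in sites:
        text = _validate_motif(site)
        if len(text) != 6:
            raise ValueError(f"recognition site {site!r} is not length 6")
        seed = seed_for(composition_of(text))
        if seed is None:
            logger.warning(
                "site %s has a non-self-complementary composition; skipped", text
            )
        out[text] = seed
    return out
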