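"""Synthetic genomes and fragment pools with controlled base composition.

The generator emulates the two data sources of the study design: parent
genomes (>= 1 Mb bacterial chromosomes differing mainly in GC content) and
shotgun-style fragment pools (reads/contigs of fixed length — 2, 5, 10 or
30 kb in the original design — drawn uniformly from a parent, optionally with
i.i.d. substitution errors). Bases are i.i.d. with P(G)=P(C)=gc/2 and
P(A)=P(T)=(1-gc)/2; specific motifs can additionally be planted at random
non-overlapping positions. Everything is reproducible from integer seeds:
identical seeds give byte-identical output.

Deliberately not modelled: homopolymer/indel error profiles, coverage
distributions, repeats and oligonucleotide autocorrelation of real genomes.
The i.i.d. model is sufficient to stress the coverage-proportion statistic,
which depends only on base/motif composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .counting import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class GenomeSpec:
    """Recipe for one synthetic parent genome."""

    length: int
    gc_content: float
    seed: int = 0
    planted_motifs: Optional[Sequence[tuple[str, int]]] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"gc_content must be in [0, 1], got {self.gc_content}")
        if self.planted_motifs:
            load = sum(len(m) * c for m, c in self.planted_motifs)
            if load > self.length:
                raise ValueError(
                    f"planted motifs need {load} bases but genome is {self.length}"
                )


@dataclass
class FragmentSpec:
    """Recipe for a batch of fixed-length fragments from one genome."""

    n: int
    length: int
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1:
            raise ValueError("fragment count and length must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")


def synth_genome(spec: GenomeSpec) -> SequenceRecord:
    """Draw an i.i.d. genome at the requested GC content; plant motifs if asked.

    Planted copies are written at uniformly chosen, mutually non-overlapping
    positions (rejection-sampled; an over-full request raises).
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=spec.length, p=p).astype(np.uint8)
    if spec.planted_motifs:
        occupied: list[tuple[int, int]] = []
        for motif, copies in spec.planted_motifs:
            mbytes = np.frombuffer(motif.upper().encode(), dtype=np.uint8)
            mcodes = _CODE[mbytes]
            if (mcodes == 255).any():
                raise ValueError(f"planted motif {motif!r} is not over ACGT")
            L = len(motif)
            placed = 0
            tries = 0
            max_tries = 200 * copies + 1000
            while placed < copies:
                tries += 1
                if tries > max_tries:
                    raise ValueError(
                        f"could not place {copies} non-overlapping copies of "
                        f"{motif!r} in {spec.length} bases"
                    )
                start = int(rng.integers(0, spec.length - L + 1))
                if any(start < e and start + L > s for s, e in occupied):
                    continue
                codes[start:start + L] = mcodes
                occupied.append((start, start + L))
                placed += 1
    residues = _BASES[codes].tobytes().decode()
    gid = spec.id or f"synth_gc{spec.gc_content:.2f}_s{spec.seed}"
    return SequenceRecord(
        id=gid,
        residues=residues,
        description=f"synthetic genome length={spec.length} gc={spec.gc_content:.3f} seed={spec.seed}",
    )


def sample_fragments(genome: SequenceRecord, spec: FragmentSpec) -> list[SequenceRecord]:
    """Draw fixed-length fragments from uniform start positions.

    Substitution errors are applied i.i.d. at ``error_rate`` per base (the
    substituted base is always different from the original; non-ACGT
    positions are left untouched). Fragment ids encode parent, index and
    0-based start: ``{parent}|f{i}|{start}``.
    """
    if spec.length > len(genome):
        raise ValueError(
            f"fragment length {spec.length} exceeds genome length {len(genome)}"
        )
    rng = np.random.default_rng(spec.seed)
    starts = rng.integers(0, len(genome) - spec.length + 1, size=spec.n)
    out = []
    for i, start in enumerate(starts):
        start = int(start)
        sub = genome.residues[start:start + spec.length]
        if spec.error_rate > 0:
            codes = _CODE[np.frombuffer(sub.encode(), dtype=np.uint8)].copy()
            hit = (rng.random(spec.length) < spec.error_rate) & (codes != 255)
            n_hit = int(hit.sum())
            if n_hit:
                shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
                codes[hit] = (codes[hit] + shift) % 4
            sub = _decode(codes, sub)
        out.append(SequenceRecord(
            id=f"{genome.id}|f{i}|{start}",
            residues=sub,
            description=f"fragment of {genome.id} start={start} len={spec.length}",
        ))
    return out


def _decode(codes: np.ndarray, original: str) -> str:
    """Codes back to letters, passing non-ACGT positions through unchanged."""
    raw = np.frombuffer(original.encode(), dtype=np.uint8).copy()
    valid = codes != 255
    raw[valid] = _BASES[codes[valid]]
    return raw.tobytes().decode()


@dataclass
class PoolResult:
    """Parents, a shuffled mixed fragment pool, and the origin truth table."""

    parents: list[SequenceRecord]
    fragments: list[SequenceRecord]
    truth: dict[str, str]

    def write(self, out_dir) -> dict[str, Path]:
        """Write parents.fasta, pool.fasta and truth.tsv; returns the paths."""
        from .io import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "parents": out / "parents.fasta",
            "pool": out / "pool.fasta",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.parents, paths["parents"])
        write_fasta(self.fragments, paths["pool"])
        with open(paths["truth"], "w") as fh:
            fh.write("fragment_id\tparent_id\n")
            for frag in self.fragments:
                fh.write(f"{frag.id}\t{self.truth[frag.id]}\n")
        return paths


def make_pool(
    parent_specs: Sequence[GenomeSpec], frag_spec: FragmentSpec
) -> PoolResult:
    """Build a mixed pool: synthesise parents, fragment each, shuffle together.

    Per-parent fragment batches get distinct deterministic child seeds derived
    from ``frag_spec.seed``; the pooled fragment order is a seeded shuffle, so
    binning code cannot exploit input grouping.
    """
    if not parent_specs:
        raise ValueError("at least one parent genome spec is required")
    parents = [synth_genome(s) for s in parent_specs]
    ids = [p.id for p in parents]
    if len(set(ids)) != len(ids):
        raise ValueError(f"parent ids are not unique: {ids}")
    fragments: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for i, parent in enumerate(parents):
        child = FragmentSpec(
            n=frag_spec.n,
            length=frag_spec.length,
            seed=(frag_spec.seed * 1000003 + 7919 * i) % (2**31),
            error_rate=frag_spec.error_rate,
        )
        for frag in sample_fragments(parent, child):
            fragments.append(frag)
            truth[frag.id] = parent.id
    order = np.random.default_rng(frag_spec.seed).permutation(len(fragments))
    fragments = [fragments[int(j)] for j in order]
    return PoolResult(parents=parents, fragments=fragments, truth=truth)
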