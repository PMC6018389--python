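"""Deterministic synthetic data: FASTQ, TinySeq XML and phylogenetic trees.

Everything is reproducible from ``(seed, config)`` alone — no network, no
bundled data files.  The generators deliberately include the awkward
cases real files contain: quality lines that start with ``@``,
line-wrapped sequence and quality strings, XML sequence text broken
across lines, and (optionally) highly repetitive sequence composition,
which zlib compresses far better than uniform-random residues and which
therefore exercises the compression-ratio machinery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic generators.

    ``adversarial_rate`` is the fraction of FASTQ reads whose quality
    string is forced to start with ``@`` (the classic parsing trap);
    ``wrap_rate`` the fraction written with line-wrapped sequence and
    quality.  ``repeat_rich`` switches sequence composition from uniform
    residues to tandem ``ACGT`` repeats.
    """

    seed: int = 0
    n_records: int = 100
    length_range: tuple[int, int] = (50, 150)
    alphabet: str = "nucleotide"  # or "protein"
    quality_range: tuple[int, int] = (33, 126)
    adversarial_rate: float = 0.1
    wrap_rate: float = 0.1
    wrap_width: int = 30
    repeat_rich: bool = False
    n_trees: int = 10
    leaves_range: tuple[int, int] = (10, 100)

    def __post_init__(self) -> None:
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range min > max")
        if self.leaves_range[0] > self.leaves_range[1]:
            raise ValueError("leaves_range min > max")
        if not (33 <= self.quality_range[0] <= self.quality_range[1] <= 126):
            raise ValueError("quality_range must lie within ASCII 33-126")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    @property
    def residues(self) -> str:
        return NUCLEOTIDES if self.alphabet == "nucleotide" else AMINO_ACIDS


def _sequence(rng: random.Random, cfg: FixtureConfig, length: int) -> str:
    if cfg.repeat_rich:
        unit = "ACGT" if cfg.alphabet == "nucleotide" else "ACDE"
        offset = rng.randrange(len(unit))
        return (unit * (length // len(unit) + 2))[offset:offset + length]
    return "".join(rng.choice(cfg.residues) for _ in range(length))


def _wrap(text: str, width: int) -> Iterator[str]:
    for i in range(0, len(text), width):
        yield text[i:i + width]


def gen_fastq(cfg: FixtureConfig) -> str:
    """Synthetic FASTQ text, one deterministic corpus per (seed, config)."""
    rng = random.Random(cfg.seed)
    lo, hi = cfg.quality_range
    out: list[str] = []
    for i in range(cfg.n_records):
        length = rng.randint(*cfg.length_range)
        seq = _sequence(rng, cfg, length)
        qual = "".join(chr(rng.randint(lo, hi)) for _ in range(length))
        if length and rng.random() < cfg.adversarial_rate:
            qual = "@" + qual[1:]
        out.append(f"@r{i} spot={i + 1}")
        if rng.random() < cfg.wrap_rate:
            out.extend(_wrap(seq, cfg.wrap_width))
            out.append("+")
            out.extend(_wrap(qual, cfg.wrap_width))
        else:
            out.extend([seq, "+", qual])
    return "\n".join(out) + ("\n" if out else "")


def gen_tinyseq_xml(cfg: FixtureConfig) -> str:
    """Synthetic TinySeq XML with the sequence type as a tag attribute and
    sequence text wrapped across lines, as Entrez emits it."""
    rng = random.Random(cfg.seed)
    out: list[str] = ['<?xml version="1.0"?>', "<TSeqSet>"]
    for i in range(cfg.n_records):
        length = rng.randint(*cfg.length_range)
        seq = _sequence(rng, cfg, length)
        taxid = rng.randint(1, 10**6)
        out.append("<TSeq>")
        out.append(f'  <TSeq_seqtype value="{cfg.alphabet}"/>')
        out.append(f"  <TSeq_accver>SYN{i:07d}.1</TSeq_accver>")
        out.append(f"  <TSeq_taxid>{taxid}</TSeq_taxid>")
        out.append(f"  <TSeq_orgname>Synthetica exempli</TSeq_orgname>")
        out.append(f"  <TSeq_defline>synthetic {cfg.alphabet} sequence {i}</TSeq_defline>")
        out.append(f"  <TSeq_length>{length}</TSeq_length>")
        out.append("  <TSeq_sequence>")
        out.extend(_wrap(seq, 70))
        out.append("</TSeq_sequence>")
        out.append("</TSeq>")
    out.append("</TSeqSet>")
    return "\n".join(out) + "\n"


def gen_newick_tree(rng: random.Random, n_leaves: int) -> str:
    """One random rooted binary tree by successive random joins.

    Leaves are ``t1..tn``; every non-root branch carries a length drawn
    uniformly from [0.001, 1.0], rounded to 6 decimals so text round-trips
    are exact.
    """
    if n_leaves < 1:
        raise ValueError("a tree needs at least one leaf")
    frags = [f"t{i + 1}" for i in range(n_leaves)]
    while len(frags) > 1:
        i = rng.randrange(len(frags))
        a = frags.pop(i)
        j = rng.randrange(len(frags))
        b = frags.pop(j)
        bla = round(rng.uniform(0.001, 1.0), 6)
        blb = round(rng.uniform(0.001, 1.0), 6)
        frags.append(f"({a}:{bla},{b}:{blb})")
    return frags[0] + ";"


def gen_trees(cfg: FixtureConfig) -> list[str]:
    """A list of random Newick trees sized by ``n_trees`` and ``leaves_range``."""
    rng = random.Random(cfg.seed)
    return [gen_newick_tree(rng, rng.randint(*cfg.leaves_range))
            for _ in range(cfg.n_trees)]


def gen_nexml(cfg: FixtureConfig) -> str:
    """The same random trees as :func:`gen_trees`, as one NeXML document."""
    import dendropy
    newicks = gen_trees(cfg)
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=tns)
    for i, nwk in enumerate(newicks):
        t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns,
                              preserve_underscores=True)
        t.label = f"tree{i}"
        trees.append(t)
    return trees.as_string(schema="nexml")
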