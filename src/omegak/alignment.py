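"""In-frame codon alignments and FASTA IO."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import CODON_INDEX, codon_compatibility, translate

logger = logging.getLogger(__name__)


@dataclass
class CodonAlignment:
    """Gap-permitted, in-frame nucleotide alignment over sense codons.

    ``codes[i, s]`` is the codon index of taxon ``i`` at codon site
    ``s``, or -1 where the codon is gapped or ambiguous (treated as
    missing data by the likelihood, which then sums over the compatible
    codons recorded in :meth:`leaf_partials`).
    """

    taxa: list[str]
    seqs: list[str]
    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa and seqs must have the same length")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if not self.seqs:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not divisible by 3")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        self._check_stops()
        self.codes = self._encode()

    def _check_stops(self):
        for taxon, seq in zip(self.taxa, self.seqs):
            for s in range(0, len(seq), 3):
                codon = seq[s : s + 3]
                if set(codon) <= set("ACGT") and translate(codon) == "*":
                    raise ValueError(
                        f"stop codon {codon} at codon site {s // 3} in {taxon!r}"
                    )

    def _encode(self) -> np.ndarray:
        n, m = len(self.taxa), self.n_codons
        codes = np.full((n, m), -1, dtype=np.int16)
        for i, seq in enumerate(self.seqs):
            for s in range(m):
                idx = CODON_INDEX.get(seq[3 * s : 3 * s + 3])
                if idx is not None:
                    codes[i, s] = idx
        return codes

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def leaf_partials(self) -> np.ndarray:
        """Boolean (n_taxa, n_codons, 61) compatibility masks."""
        n, m = self.n_taxa, self.n_codons
        mask = np.zeros((n, m, 61), dtype=bool)
        resolved = self.codes >= 0
        idx = np.where(resolved)
        mask[idx[0], idx[1], self.codes[idx]] = True
        for i, s in zip(*np.where(~resolved)):
            mask[i, s] = codon_compatibility(self.seqs[i][3 * s : 3 * s + 3])
        return mask

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        by_name = {t: s for t, s in zip(self.taxa, self.seqs)}
        missing = [t for t in taxa if t not in by_name]
        if missing:
            raise ValueError(f"taxa not in alignment: {missing}")
        return CodonAlignment(list(taxa), [by_name[t] for t in taxa])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) tuples.

    Lowercase input is normalised to uppercase (with a logged note);
    duplicate ids are rejected.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"malformed FASTA in {path}: line {lineno} precedes any "
                        f"'>' header"
                    )
                break
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    lowered = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            lowered = True
            seq = seq.upper()
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append((rec.id, seq))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate sequence ids in {path}: {dupes}")
    if lowered:
        logger.info("normalised lowercase sequence letters to uppercase in %s", path)
    return records


def write_fasta(records, path: str | Path, width: int = 80) -> None:
    """Write (id, sequence) tuples as FASTA wrapped at ``width`` columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    records = read_fasta(path)
    if not records:
        raise ValueError(f"empty alignment file: {path}")
    return CodonAlignment([r[0] for r in records], [r[1] for r in records])


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    write_fasta(zip(aln.taxa, aln.seqs), path)
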