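"""Amplicon design: the reference coding sequence and read-processing thresholds.

The design object carries everything the read-to-count stage needs to know
about the assay: the wild-type coding sequence of the mutagenised region
(126 nt = 42 codons for the amyloid-beta peptide), the constant flanks used
for trimming, and the quality/length acceptance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio import SeqIO

#: Amyloid-beta 1-42 peptide sequence (positions numbered D1..A42).
ABETA42_AA = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str) -> str:
    """Translate a coding nucleotide sequence with the standard code ('*' = stop)."""
    return str(Seq(nt_seq).translate())


@dataclass
class AmpliconDesign:
    """Assay geometry and read-filter thresholds.

    Parameters
    ----------
    wt_coding_seq : str
        Wild-type coding sequence of the variant region. Must be a multiple
        of 3 and translate without internal stop codons.
    flank5, flank3 : str
        Constant regions flanking the variant region in the amplicon
        (given on the forward strand).
    max_flank_mismatch_rate : float
        Read pairs whose constant regions mismatch the reference at a higher
        fraction of positions are discarded.
    min_phred : int
        Base-quality threshold applied to the merged consensus.
    expected_len : int
        Required consensus length; reads of any other length (indels) are
        discarded.
    min_overlap : int
        Minimum mate overlap required to merge a pair.
    quality_rule : str
        'min' (every base >= min_phred) or 'mean' (average >= min_phred).
    """

    wt_coding_seq: str
    flank5: str = ""
    flank3: str = ""
    max_flank_mismatch_rate: float = 0.2
    min_phred: int = 30
    expected_len: int = field(default=0)
    min_overlap: int = 20
    quality_rule: str = "min"

    def __post_init__(self) -> None:
        self.wt_coding_seq = self.wt_coding_seq.upper()
        if self.expected_len == 0:
            self.expected_len = len(self.wt_coding_seq)
        if len(self.wt_coding_seq) % 3 != 0:
            raise ValueError("wt_coding_seq length must be a multiple of 3")
        aa = translate(self.wt_coding_seq)
        if "*" in aa:
            raise ValueError("wt_coding_seq translation contains a stop codon")
        if self.quality_rule not in ("min", "mean"):
            raise ValueError("quality_rule must be 'min' or 'mean'")

    @property
    def wt_aa_seq(self) -> str:
        return translate(self.wt_coding_seq)

    @property
    def n_codons(self) -> int:
        return len(self.wt_coding_seq) // 3

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "AmpliconDesign":
        """Build a design from a single-record FASTA holding the WT coding sequence."""
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(wt_coding_seq=str(record.seq), **kwargs)
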