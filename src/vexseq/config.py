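"""Configuration dataclasses: design rules, read layout, reporter backbone.

The defaults encode the assay's published design rules (flank minima, exon
length window, barcode count/length, primer and restriction sequences) and a
synthetic reporter backbone used by the simulator and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import VexSeqError
from .util import is_dna

#: Restriction sites used in the two-step cloning of the reporter insert.
#: All four recognition sequences are palindromic, so scanning the sense
#: strand covers both orientations.
DEFAULT_RESTRICTION_MOTIFS = {
    "PstI": "CTGCAG",
    "XbaI": "TCTAGA",
    "SpeI": "ACTAGT",
    "MfeI": "CAATTG",
}

#: Library-wide amplification primers (the common primer set used to amplify
#: the synthesized oligo pool).
DEFAULT_FWD_PRIMER = "GTAGCGTCTGTCCGTCTGCA"
DEFAULT_REV_PRIMER = "CTGTAGTAGTAGTTGTCTAG"

#: PCR primer that sits at the start of read 1, inside constitutive exon 1.
EXON1_READ1_PRIMER = "GGCAAGGTGAACGTGGATGAAG"

#: Gene-specific half of the reverse-transcription primer: it anneals in the
#: 3' UTR downstream of the barcode, so its sequence appears verbatim in
#: read 2 immediately after the 10-nt UMI.
DEFAULT_UTR_ANCHOR = "GCAACTAGAAGGCACAGTCGAGG"


@dataclass(frozen=True)
class DesignConfig:
    """Design rules for the oligo library.

    Lengths are nucleotides. ``pyrimidine_tract`` is the 20-nt tract written
    into consensus splice-site controls; the alternating TC default is a
    deterministic pyrimidine-only choice.
    """

    min_up_flank: int = 50
    min_down_flank: int = 20
    min_exon_len: int = 68
    max_exon_len: int = 97
    min_barcodes: int = 3
    barcode_len: int = 8
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    restriction_motifs: dict = field(
        default_factory=lambda: dict(DEFAULT_RESTRICTION_MOTIFS)
    )
    site_5: str = "PstI"
    site_mid: tuple = ("MfeI", "SpeI")
    site_3: str = "XbaI"
    max_oligo_len: int = 300
    pyrimidine_tract: str = "TC" * 10
    #: extra genomic context (each side) retained so deletions can be padded
    #: back to the flank minima
    flank_context: int = 30
    min_barcode_hamming: int = 2

    def __post_init__(self):
        if not self.fwd_primer or not self.rev_primer:
            raise VexSeqError("primer sequences must be non-empty")
        for name, motif in self.restriction_motifs.items():
            if not is_dna(motif):
                raise VexSeqError(f"restriction motif {name}={motif!r} is not DNA")
        if not is_dna(self.pyrimidine_tract) or set(self.pyrimidine_tract) - set("CT"):
            raise VexSeqError("pyrimidine tract must contain only C/T")

    def motif(self, name: str) -> str:
        return self.restriction_motifs[name]


@dataclass(frozen=True)
class Backbone:
    """Constitutive-exon sequences of the mini-gene reporter.

    ``exon1_suffix`` is the portion of exon 1 covered by read 1 starting at
    the read-1 PCR primer; ``exon3`` is the third (final) exon. The default
    instance below is a synthetic stand-in for the plasmid backbone, which is
    not distributed with the package.
    """

    exon1_suffix: str
    exon3: str

    def __post_init__(self):
        if not (is_dna(self.exon1_suffix) and is_dna(self.exon3)):
            raise VexSeqError("backbone sequences must be DNA")


#: Synthetic backbone: exon 1 begins with the read-1 PCR primer; both
#: sequences were chosen once to be free of the cloning restriction motifs.
DEFAULT_BACKBONE = Backbone(
    exon1_suffix=EXON1_READ1_PRIMER + "CACCTTGGACCCAGAGGTTC",
    exon3="CTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAACGTGGATTAAGTTG",
)


@dataclass(frozen=True)
class ReadLayout:
    """Structure of the RNA amplicon read pair.

    Read 2 (as sequenced): 10-nt UMI, then the gene-specific UTR anchor, then
    the reverse complement of the transcript walking back across the barcode
    cassette: XbaI site, revcomp(barcode), SpeI site, revcomp(exon 3).
    """

    umi_len: int = 10
    utr_anchor: str = DEFAULT_UTR_ANCHOR
    barcode_site: str = DEFAULT_RESTRICTION_MOTIFS["XbaI"]
    inner_site: str = DEFAULT_RESTRICTION_MOTIFS["SpeI"]
    barcode_len: int = 8
    exon3_check_len: int = 10
    max_anchor_mismatch: int = 1
    read_len: int = 150

    @property
    def site_offset(self) -> int:
        return self.umi_len + len(self.utr_anchor)

    @property
    def barcode_offset(self) -> int:
        return self.site_offset + len(self.barcode_site)

    @property
    def inner_site_offset(self) -> int:
        return self.barcode_offset + self.barcode_len

    @property
    def exon3_offset(self) -> int:
        return self.inner_site_offset + len(self.inner_site)

    def __post_init__(self):
        if self.umi_len != 10:
            raise VexSeqError("UMI length is fixed at 10 nt by the assay design")
        if self.exon3_offset + self.exon3_check_len > self.read_len:
            raise VexSeqError("read-2 layout does not fit in the read length")
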