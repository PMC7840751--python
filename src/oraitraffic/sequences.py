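"""Orai construct panel: typed protein sequences, substitutions and truncations.

Every residue position in this package is a 1-based index into the full-length
protein (UniProt numbering), even on extracted fragments — the positions the
trafficking literature quotes (CBM 52–60, the F270/F279 FXXΦ motifs, L273, the
1–266/1–275/1–285 truncations) are all full-length positions, and keeping a
single numbering frame removes an entire class of off-by-one errors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class SequenceError(ValueError):
    """Raised for malformed sequences or invalid mutation specifications."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence carrying its full-length numbering frame.

    ``numbering_offset`` is the 1-based full-length index of the first stored
    residue, so a C-terminal fragment extracted at 260 still answers queries
    about residue 270 correctly.
    """

    id: str
    residues: str
    description: str = ""
    numbering_offset: int = 1
    cterm_start: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")
        for i, aa in enumerate(self.residues):
            if aa not in _AA_SET:
                raise SequenceError(
                    f"{self.id}: illegal residue letter {aa!r} at position "
                    f"{self.numbering_offset + i}"
                )
        if self.numbering_offset < 1:
            raise SequenceError(f"{self.id}: numbering_offset must be >= 1")
        if self.cterm_start is not None and not (
            self.numbering_offset <= self.cterm_start <= self.end
        ):
            raise SequenceError(
                f"{self.id}: cterm_start {self.cterm_start} outside "
                f"[{self.numbering_offset}, {self.end}]"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end(self) -> int:
        """Full-length index of the last stored residue."""
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Residue letter at a 1-based full-length position."""
        if not self.numbering_offset <= position <= self.end:
            raise SequenceError(
                f"{self.id}: position {position} outside "
                f"[{self.numbering_offset}, {self.end}]"
            )
        return self.residues[position - self.numbering_offset]

    def positions(self) -> range:
        """Full-length positions covered by this sequence."""
        return range(self.numbering_offset, self.end + 1)


@dataclass(frozen=True)
class MutationSpec:
    """An ordered set of point substitutions plus an optional truncation.

    Substitutions are applied first, the truncation afterwards, so the two
    compose deterministically the way the constructs are named (e.g. a
    truncated double mutant). ``from_aa`` is checked against the target
    sequence to guard against numbering slips.
    """

    name: str
    substitutions: tuple[tuple[int, str, str], ...] = ()
    truncate_after: int | None = None

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if positions != sorted(set(positions)):
            raise SequenceError(
                f"{self.name}: substitution positions must be strictly increasing"
            )
        for pos, src, dst in self.substitutions:
            if src not in _AA_SET or dst not in _AA_SET:
                raise SequenceError(
                    f"{self.name}: non-standard residue in substitution "
                    f"{src}{pos}{dst}"
                )

    @classmethod
    def parse(cls, name: str, mutations: str = "", truncate_after: int | None = None
              ) -> "MutationSpec":
        """Build a spec from compact notation like ``"F270A,F279A"``."""
        subs = []
        for token in filter(None, (t.strip() for t in mutations.split(","))):
            src, pos, dst = token[0], int(token[1:-1]), token[-1]
            subs.append((pos, src, dst))
        subs.sort(key=lambda s: s[0])
        return cls(name=name, substitutions=tuple(subs), truncate_after=truncate_after)


def apply_mutation(seq: ProteinSequence, spec: MutationSpec) -> ProteinSequence:
    """Apply a :class:`MutationSpec` to a sequence, returning a new sequence.

    Raises :class:`SequenceError` when ``from_aa`` does not match the template
    at a position, or a position/truncation point falls outside the sequence.
    """
    chars = list(seq.residues)
    for pos, src, dst in spec.substitutions:
        if not seq.numbering_offset <= pos <= seq.end:
            raise SequenceError(
                f"{spec.name}: substitution position {pos} outside "
                f"[{seq.numbering_offset}, {seq.end}] of {seq.id}"
            )
        found = seq.residue_at(pos)
        if found != src:
            raise SequenceError(
                f"{spec.name}: expected {src} at position {pos} of {seq.id}, "
                f"found {found}"
            )
        chars[pos - seq.numbering_offset] = dst
    residues = "".join(chars)
    if spec.truncate_after is not None:
        if not seq.numbering_offset <= spec.truncate_after <= seq.end:
            raise SequenceError(
                f"{spec.name}: truncate_after {spec.truncate_after} outside "
                f"[{seq.numbering_offset}, {seq.end}] of {seq.id}"
            )
        residues = residues[: spec.truncate_after - seq.numbering_offset + 1]
    cterm = seq.cterm_start
    if cterm is not None and spec.truncate_after is not None and cterm > spec.truncate_after:
        cterm = None
    return ProteinSequence(
        id=spec.name,
        residues=residues,
        description=f"{seq.id} + {spec.name}",
        numbering_offset=seq.numbering_offset,
        cterm_start=cterm,
    )


def extract_cterm(seq: ProteinSequence, start: int) -> ProteinSequence:
    """Extract the fragment from full-length position ``start`` to the end.

    The fragment keeps full-length numbering via ``numbering_offset``, so
    extraction is idempotent at a fixed start.
    """
    if not seq.numbering_offset <= start <= seq.end:
        raise SequenceError(
            f"{seq.id}: cterm start {start} outside [{seq.numbering_offset}, {seq.end}]"
        )
    return ProteinSequence(
        id=seq.id,
        residues=seq.residues[start - seq.numbering_offset:],
        description=f"{seq.id} residues {start}-{seq.end}",
        numbering_offset=start,
        cterm_start=start if seq.cterm_start is None or seq.cterm_start < start
        else seq.cterm_start,
    )


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file into :class:`ProteinSequence` records.

    Sequences are uppercased; any letter outside the 20-residue alphabet is a
    hard error naming the record and 1-based position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        for i, aa in enumerate(raw):
            if aa not in _AA_SET:
                raise SequenceError(
                    f"{path.name}:{rec.id}: illegal residue letter {aa!r} "
                    f"at position {i + 1}"
                )
        records.append(
            ProteinSequence(id=rec.id, residues=raw, description=rec.description)
        )
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# The construct panel assayed for internalization during meiosis: wild type,
# three nested C-terminal truncations, the FXXΦ phenylalanine mutants, the
# coil-stabilizing A277,280L design, the coil-breaking L273S, and the caveolin
# binding motif mutants.
PANEL_SPECS: tuple[MutationSpec, ...] = (
    MutationSpec.parse("WT"),
    MutationSpec.parse("1-266", truncate_after=266),
    MutationSpec.parse("1-275", truncate_after=275),
    MutationSpec.parse("1-285", truncate_after=285),
    MutationSpec.parse("F270A", "F270A"),
    MutationSpec.parse("F279A", "F279A"),
    MutationSpec.parse("F270,279A", "F270A,F279A"),
    MutationSpec.parse("A277,280L", "A277L,A280L"),
    MutationSpec.parse("L273S", "L273S"),
    MutationSpec.parse("Y52,W55A", "Y52A,W55A"),
    MutationSpec.parse("Y52,W55,F270,F279A", "Y52A,W55A,F270A,F279A"),
)


def construct_panel(wt: ProteinSequence) -> list[tuple[str, ProteinSequence]]:
    """Build the full mutant/truncation panel from a full-length hOrai1 WT.

    Output order is fixed. Every spec is validated against the supplied WT, so
    a template whose residue 270 is not F (etc.) fails loudly.
    """
    return [(spec.name, apply_mutation(wt, spec)) for spec in PANEL_SPECS]


def export_panel(panel: Sequence[tuple[str, ProteinSequence]], out_dir: str | Path
                 ) -> tuple[Path, Path]:
    """Write the panel as FASTA plus a CSV manifest (name, mutations, length)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "panel.fasta"
    manifest_path = out_dir / "panel_manifest.csv"
    write_fasta([s for _, s in panel], fasta_path)
    by_name = {spec.name: spec for spec in PANEL_SPECS}
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "substitutions", "truncate_after", "length"])
        for name, seq in panel:
            spec = by_name.get(name)
            subs = ";".join(f"{s}{p}{d}" for p, s, d in spec.substitutions) if spec else ""
            trunc = spec.truncate_after if spec else ""
            writer.writerow([name, subs, trunc if trunc else "", len(seq)])
    return fasta_path, manifest_path


def _data_path(name: str) -> Path:
    return Path(str(resources.files("oraitraffic").joinpath("data", name)))


def load_horai1() -> ProteinSequence:
    """Load the bundled full-length human Orai1 (301 aa, UniProt numbering).

    The cytosolic C-terminus starts at residue 260.
    """
    seq = read_fasta(_data_path("orai1_human.fasta"))[0]
    return replace(seq, id="hOrai1", cterm_start=260)


def load_isoform_cterms() -> list[ProteinSequence]:
    """Load the three Orai isoform C-termini used for the CC-strength series.

    hOrai1 is the genuine human sequence (residues 260-301). The two Xenopus
    entries are synthetic stand-ins constructed to reproduce the described
    C-terminal divergence of the isoforms (F279 not conserved, F270 weakly
    conserved, coiled-coil strength xOrai1 > hOrai1 > xOrai2); see the FASTA
    headers and docs/methods.md.
    """
    return read_fasta(_data_path("orai_cterm_isoforms_synthetic.fasta"))
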