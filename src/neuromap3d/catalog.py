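"""Mature-neuropeptide prediction from precursor (prohormone) sequences.

Insect neuropeptide precursors are processed by prohormone convertases at
basic cleavage sites, most reliably at dibasic motifs (KR, RR, KK, RK).
After excision, carboxypeptidases remove the flanking basic residues, a
C-terminal glycine is converted into an amide by PAM, and an N-terminal
glutamine or glutamate may cyclise into pyroglutamate.  This module turns
precursor sequences into the catalog of mature, PTM-annotated peptides
that downstream mass annotation targets.

The cleavage engine is a configurable reconstruction of that convention;
curated peptide tables can be loaded directly when the maturation is
already known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

CATALOG_COLUMNS = ["name", "species", "sequence", "amidated", "pyroglu"]


class CatalogError(ValueError):
    """Raised for malformed precursor or catalog inputs."""


@dataclass(frozen=True)
class Precursor:
    """A neuropeptide precursor (prepropeptide) sequence."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(f"precursor {self.id!r}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in CANONICAL_RESIDUES:
                raise CatalogError(
                    f"precursor {self.id!r}: non-canonical residue "
                    f"{aa!r} at position {i + 1}"
                )


@dataclass(frozen=True)
class CleavageRules:
    """Prohormone-convertase cleavage convention.

    dibasic_motifs
        Two-residue motifs after which the precursor is cut (cut falls
        AFTER the second basic residue).
    allow_monobasic
        Also cut after isolated K/R sites.  Off by default: monobasic
        processing is real but has a high false-positive rate.
    min_len, max_len
        Length bounds (residues) applied to candidates after trimming.
    trim_flanking_basic
        Remove leading/trailing K/R left on a candidate by cleavage
        (carboxypeptidase E step).
    """

    dibasic_motifs: frozenset[str] = frozenset({"KR", "RR", "KK", "RK"})
    allow_monobasic: bool = False
    min_len: int = 3
    max_len: int = 50
    trim_flanking_basic: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise CatalogError("min_len must be >= 1")
        if self.min_len > self.max_len:
            raise CatalogError("min_len must be <= max_len")
        for m in self.dibasic_motifs:
            if len(m) != 2 or any(c not in "KR" for c in m):
                raise CatalogError(f"invalid dibasic motif {m!r}")
        object.__setattr__(self, "dibasic_motifs", frozenset(self.dibasic_motifs))

    @classmethod
    def from_json(cls, path: str) -> "CleavageRules":
        with open(path) as fh:
            d = json.load(fh)
        if "dibasic_motifs" in d:
            d["dibasic_motifs"] = frozenset(d["dibasic_motifs"])
        return cls(**d)


@dataclass(frozen=True)
class MaturePeptide:
    """A mature peptide with its post-translational modification state.

    ``sequence`` stores the post-processing residues: when ``amidated``
    the precursor-encoded C-terminal glycine has already been removed.
    """

    sequence: str
    amidated: bool = False
    pyroglu: bool = False
    name: str = ""
    precursor_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError("mature peptide: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in CANONICAL_RESIDUES:
                raise CatalogError(
                    f"peptide {self.name or self.sequence!r}: non-canonical "
                    f"residue {aa!r} at position {i + 1}"
                )
        if self.pyroglu and self.sequence[0] not in "QE":
            raise CatalogError(
                f"peptide {self.name or self.sequence!r}: pyroglutamate "
                "requires an N-terminal Q or E"
            )

    @property
    def display_name(self) -> str:
        return self.name or self.display_sequence

    @property
    def display_sequence(self) -> str:
        """Sequence in reporting convention: pQ prefix, -NH2 suffix."""
        s = ("p" + self.sequence) if self.pyroglu else self.sequence
        return s + ("-NH2" if self.amidated else "")


def read_precursor_fasta(path: str, species: str = "") -> list[Precursor]:
    """Read precursors from a FASTA file (id = first header token)."""
    records = list(SeqIO.parse(path, "fasta"))
    return [
        Precursor(id=r.id, sequence=str(r.seq).upper(), species=species)
        for r in records
    ]


def _cut_points(seq: str, rules: CleavageRules) -> list[int]:
    """Indices after which the sequence is cut (greedy left-to-right)."""
    cuts = []
    i = 0
    n = len(seq)
    while i < n:
        if i + 1 < n and seq[i : i + 2] in rules.dibasic_motifs:
            cuts.append(i + 2)
            i += 2
        elif rules.allow_monobasic and seq[i] in "KR":
            cuts.append(i + 1)
            i += 1
        else:
            i += 1
    return cuts


def cleave_precursor(p: Precursor, rules: CleavageRules | None = None) -> list[str]:
    """Cut a precursor at basic sites and return candidate peptides.

    Candidates are the maximal substrings between cleavage sites (the cut
    falls after the second residue of a dibasic motif), with flanking
    basic residues optionally trimmed and length bounds applied.  Order
    of appearance is preserved; an empty list is a valid result.
    """
    rules = rules or CleavageRules()
    seq = p.sequence
    bounds = [0] + _cut_points(seq, rules) + [len(seq)]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        frag = seq[a:b]
        if rules.trim_flanking_basic:
            frag = frag.strip("KR")
        if rules.min_len <= len(frag) <= rules.max_len:
            out.append(frag)
    return out


def apply_ptms(
    candidate: str,
    enable_amidation: bool = True,
    enable_pyroglu: bool = True,
    *,
    name: str = "",
    precursor_id: str = "",
    species: str = "",
) -> list[MaturePeptide]:
    """Enumerate PTM variants of a cleavage candidate.

    The unmodified candidate is always emitted.  If the candidate ends in
    glycine and amidation is enabled, the amidated variant (terminal G
    removed) is added; if it starts with Q or E and pyroglutamate
    formation is enabled, the cyclised variant is added; the combination
    is enumerated as well.  Duplicates are removed, order preserved.
    """
    if not candidate:
        raise CatalogError("apply_ptms: empty candidate")
    meta = dict(name=name, precursor_id=precursor_id, species=species)
    variants: list[MaturePeptide] = [MaturePeptide(candidate, **meta)]
    can_amidate = enable_amidation and candidate.endswith("G") and len(candidate) > 1
    can_pyroglu = enable_pyroglu and candidate[0] in "QE"
    if can_amidate:
        variants.append(MaturePeptide(candidate[:-1], amidated=True, **meta))
    if can_pyroglu:
        variants.append(MaturePeptide(candidate, pyroglu=True, **meta))
    if can_amidate and can_pyroglu and len(candidate) > 1:
        variants.append(
            MaturePeptide(candidate[:-1], amidated=True, pyroglu=True, **meta)
        )
    seen: set[tuple] = set()
    out = []
    for v in variants:
        key = (v.sequence, v.amidated, v.pyroglu)
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def build_catalog(
    precursors: list[Precursor],
    rules: CleavageRules | None = None,
    enable_amidation: bool = True,
    enable_pyroglu: bool = True,
) -> list[MaturePeptide]:
    """Cleave every precursor and enumerate PTM variants of each candidate."""
    rules = rules or CleavageRules()
    catalog: list[MaturePeptide] = []
    for p in precursors:
        for j, cand in enumerate(cleave_precursor(p, rules), start=1):
            catalog.extend(
                apply_ptms(
                    cand,
                    enable_amidation,
                    enable_pyroglu,
                    name=f"{p.id}_{j}",
                    precursor_id=p.id,
                    species=p.species,
                )
            )
    return catalog


def read_catalog_csv(path: str) -> list[MaturePeptide]:
    """Load a curated catalog CSV (name,species,sequence,amidated,pyroglu)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            MaturePeptide(
                sequence=row["sequence"].strip().upper(),
                amidated=_parse_bool(row["amidated"]),
                pyroglu=_parse_bool(row["pyroglu"]),
                name=row["name"],
                species=row["species"],
                precursor_id=str(row.get("precursor_id", "") or ""),
            )
        )
    return out


def write_catalog_csv(catalog: list[MaturePeptide], path: str) -> None:
    df = pd.DataFrame(
        {
            "name": [p.name for p in catalog],
            "species": [p.species for p in catalog],
            "sequence": [p.sequence for p in catalog],
            "amidated": [p.amidated for p in catalog],
            "pyroglu": [p.pyroglu for p in catalog],
            "precursor_id": [p.precursor_id for p in catalog],
        }
    )
    df.to_csv(path, index=False)


def _parse_bool(s: str) -> bool:
    return str(s).strip().lower() in {"1", "true", "yes", "y", "t"}
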