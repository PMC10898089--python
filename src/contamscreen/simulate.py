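"""Synthetic taxonomies, genomes, and contamination fixtures.

Everything the screen needs can be simulated without downloads: a mock
taxonomy spanning the eight kingdoms, random ancestral genomes per species,
diverged strains (substitution-dominated, transition:transversion 2:1 by
default, plus rare short indels), fragmented query sets at defined sizes
(1 / 10 / 100 kbp), host+contaminant mixtures (5% contamination by length
in 1-kbp pieces by default), and chimeric fusions of a 100-kbp host piece
with a single 1-kbp contaminant fragment, optionally separated by 10 Ns.

Planted features exercise the masking and thresholding logic: a shared
"conserved" segment inserted into every eukaryote species (so eukaryote
queries see >= 5 divisions align over it) and a transposon-like repeat
family copied tens of times into each eukaryote genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import EUKARYOTE_KINGDOMS, TaxonomyTable

__all__ = [
    "SimSpec",
    "ReferenceSet",
    "derive_strain",
    "generate_query_set",
    "generate_reference_set",
    "random_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the synthetic fixtures.

    Defaults give a desk-scale world: one or two species per division,
    prokaryote genomes of 150 kbp and eukaryote genomes of 300 kbp, strain
    divergence of 2% substitutions with rare short indels, two 2-kbp
    conserved elements shared across all eukaryote species, and a 3-kbp
    repeat family at 30 copies per eukaryote genome.
    """

    #: division -> (kingdom, number of species)
    divisions: tuple[tuple[str, tuple[str, int]], ...] = (
        ("prok:g-proteobacteria", ("Bacteria", 2)),
        ("prok:a-proteobacteria", ("Bacteria", 1)),
        ("arch:euryarchaeotes", ("Archaea", 1)),
        ("anml:primates", ("Metazoa", 2)),
        ("anml:insects", ("Metazoa", 1)),
        ("fung:ascomycetes", ("Fungi", 1)),
        ("plnt:monocots", ("Viridiplantae", 1)),
        ("prot:apicomplexans", ("other-Eukaryota", 1)),
        ("virs:prokaryotic viruses", ("Viruses", 1)),
    )
    prokaryote_genome_bp: int = 150_000
    eukaryote_genome_bp: int = 300_000
    virus_genome_bp: int = 20_000
    gc_fraction: float = 0.45
    strain_divergence: float = 0.02  #: substitutions/site between strain and ancestor
    strain_indel_rate: float = 0.0005  #: indels/site, geometric lengths (mean ~3)
    intra_division_divergence: float = 0.10  #: between species sharing a division
    transition_transversion: float = 2.0
    conserved_elements: int = 2
    conserved_element_bp: int = 2_000
    repeat_copies: int = 30
    repeat_element_bp: int = 3_000
    repeat_copy_divergence: float = 0.02
    fragment_sizes: tuple[int, ...] = (1_000, 10_000, 100_000)
    contamination_fraction: float = 0.05  #: by length, in 1-kbp pieces
    contaminant_fragment_bp: int = 1_000
    chimera_host_bp: int = 100_000
    chimera_contaminant_bp: int = 1_000
    chimera_n_separator: int = 10
    n_replicates: int = 5
    base_taxid: int = 1_000_000


@dataclass
class ReferenceSet:
    """Reference genomes plus their mock taxonomy."""

    records: list[tuple[str, int, str]]  # (seq_id, taxid, sequence)
    taxonomy: TaxonomyTable
    spec: SimSpec
    seed: int
    by_taxid: dict[int, str] = field(default_factory=dict)

    def genome(self, taxid: int) -> str:
        return self.by_taxid[taxid]

    def taxids_for_division(self, division: str) -> list[int]:
        df = self.taxonomy.df
        return [int(t) for t in df.loc[df["division"] == division, "taxid"]]


def random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=length, p=p)]).decode()


def _mutate_base(base: str, rng: np.random.Generator, ts_tv: float) -> str:
    if rng.random() < ts_tv / (ts_tv + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def derive_strain(
    sequence: str,
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
    ts_tv: float = 2.0,
) -> str:
    """Derive a diverged strain by substitutions and short indels.

    Substitutions are placed at ``divergence`` per site with a
    transition:transversion ratio of ``ts_tv``; indels occur at
    ``indel_rate`` per site with geometric lengths (mean 3 bp), half
    insertions of random sequence, half deletions.
    """
    if divergence == 0 and indel_rate == 0:
        return sequence
    seq = list(sequence)
    n = len(seq)
    n_subs = rng.binomial(n, divergence)
    for pos in rng.choice(n, size=n_subs, replace=False):
        if seq[pos] in _TRANSITION:
            seq[pos] = _mutate_base(seq[pos], rng, ts_tv)
    if indel_rate > 0:
        n_indels = rng.binomial(n, indel_rate)
        positions = sorted(rng.choice(n, size=n_indels, replace=False), reverse=True)
        for pos in positions:
            length = int(rng.geometric(1 / 3.0))
            if rng.random() < 0.5:
                ins = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
                seq[pos:pos] = list(ins)
            else:
                del seq[pos : pos + length]
    return "".join(seq)


def generate_reference_set(spec: SimSpec | None = None, seed: int = 0) -> ReferenceSet:
    """Generate mock reference genomes and their taxonomy table.

    Each division holds its configured number of species; the first species
    of a division gets a random ancestral genome and later species diverge
    from it at the intra-division divergence.  Conserved elements are
    planted (identically) into every eukaryote genome and the repeat family
    into each eukaryote genome at the configured copy number.
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(seed)

    conserved = [
        random_genome(spec.conserved_element_bp, spec.gc_fraction, rng)
        for _ in range(spec.conserved_elements)
    ]
    repeat_ancestor = random_genome(spec.repeat_element_bp, spec.gc_fraction, rng)

    records: list[tuple[str, int, str]] = []
    rows = []
    taxid = spec.base_taxid
    for division, (kingdom, n_species) in spec.divisions:
        if kingdom in EUKARYOTE_KINGDOMS:
            genome_bp = spec.eukaryote_genome_bp
        elif kingdom == "Viruses":
            genome_bp = spec.virus_genome_bp
        else:
            genome_bp = spec.prokaryote_genome_bp
        ancestor = None
        for i in range(n_species):
            if ancestor is None:
                genome = random_genome(genome_bp, spec.gc_fraction, rng)
                ancestor = genome
            else:
                genome = derive_strain(
                    ancestor,
                    spec.intra_division_divergence,
                    spec.strain_indel_rate,
                    rng,
                    spec.transition_transversion,
                )
            if kingdom in EUKARYOTE_KINGDOMS:
                genome = _plant_features(genome, conserved, repeat_ancestor, spec, rng)
            tag = division.split(":", 1)[1].replace(" ", "-")
            species = f"Simulatus {tag}-{i + 1}"
            seq_id = f"ref|{taxid}"
            records.append((seq_id, taxid, genome))
            rows.append((taxid, species, division, kingdom))
            taxid += 1

    taxonomy = TaxonomyTable(pd.DataFrame(rows, columns=TaxonomyTable.COLUMNS))
    refset = ReferenceSet(records=records, taxonomy=taxonomy, spec=spec, seed=seed)
    refset.by_taxid = {t: s for _, t, s in records}
    return refset


def _plant_features(
    genome: str,
    conserved: list[str],
    repeat_ancestor: str,
    spec: SimSpec,
    rng: np.random.Generator,
) -> str:
    """Overwrite random non-overlapping loci with conserved/repeat elements."""
    seq = list(genome)
    n = len(seq)
    used: list[tuple[int, int]] = []

    def place(element: str) -> None:
        for _ in range(100):
            pos = int(rng.integers(0, max(1, n - len(element))))
            if all(pos + len(element) <= s or pos >= e for s, e in used):
                seq[pos : pos + len(element)] = list(element)
                used.append((pos, pos + len(element)))
                return

    for element in conserved:
        place(element)
    for _ in range(spec.repeat_copies):
        copy = derive_strain(
            repeat_ancestor, spec.repeat_copy_divergence, 0.0, rng,
            spec.transition_transversion,
        )
        place(copy)
    return "".join(seq)


def fragment_sequence(sequence: str, size: int, min_tail: int = 1_000) -> list[str]:
    """Cut a sequence into consecutive ``size``-bp pieces.

    The final remainder is kept as a shorter fragment when it is at least
    ``min_tail`` bp, mirroring size-selected test sets.
    """
    frags = [sequence[i : i + size] for i in range(0, len(sequence), size)]
    if frags and len(frags[-1]) < min(size, min_tail):
        frags.pop()
    return frags


@dataclass
class QuerySet:
    records: list[tuple[str, str]]  # (seq_id, sequence)
    truth: pd.DataFrame  # seq_id, role, taxid, division, kingdom

    def truth_rows(self) -> list[dict]:
        return self.truth.to_dict("records")


def _strain_of(refset: ReferenceSet, taxid: int, rng: np.random.Generator) -> str:
    spec = refset.spec
    return derive_strain(
        refset.genome(taxid),
        spec.strain_divergence,
        spec.strain_indel_rate,
        rng,
        spec.transition_transversion,
    )


def generate_query_set(
    refset: ReferenceSet,
    mode: str,
    seed: int = 0,
    host_taxid: int | None = None,
    contaminant_taxid: int | None = None,
    fragment_size: int = 10_000,
    contamination_fraction: float | None = None,
    n_chimeras: int | None = None,
    use_n_separator: bool = False,
) -> QuerySet:
    """Generate a labeled query set in one of three modes.

    ``fragments``: a strain of the host species cut into ``fragment_size``
    pieces.  ``mixture``: host 100-kbp pieces plus contaminant 1-kbp pieces
    at the configured fraction by length.  ``chimera``: each 100-kbp host
    piece fused with a single 1-kbp contaminant fragment (optionally
    separated by 10 Ns).  Truth labels accompany every record.
    """
    spec = refset.spec
    rng = np.random.default_rng(seed)
    if host_taxid is None:
        host_taxid = refset.records[0][1]
    host_lin = refset.taxonomy.resolve(host_taxid)

    records: list[tuple[str, str]] = []
    rows: list[tuple] = []

    def label(seq_id: str, role: str, taxid: int) -> None:
        lin = refset.taxonomy.resolve(taxid)
        rows.append((seq_id, role, taxid, lin.division, lin.kingdom))

    if mode == "fragments":
        strain = _strain_of(refset, host_taxid, rng)
        for i, frag in enumerate(fragment_sequence(strain, fragment_size)):
            seq_id = f"frag_{host_taxid}_{fragment_size}_{i}"
            records.append((seq_id, frag))
            label(seq_id, "host", host_taxid)

    elif mode == "mixture":
        if contaminant_taxid is None:
            raise ValueError("mixture mode needs a contaminant_taxid")
        frac = (
            contamination_fraction
            if contamination_fraction is not None
            else spec.contamination_fraction
        )
        host_strain = _strain_of(refset, host_taxid, rng)
        host_frags = fragment_sequence(host_strain, spec.chimera_host_bp)
        for i, frag in enumerate(host_frags):
            seq_id = f"host_{host_taxid}_{i}"
            records.append((seq_id, frag))
            label(seq_id, "host", host_taxid)
        host_bp = sum(len(f) for f in host_frags)
        contam_strain = _strain_of(refset, contaminant_taxid, rng)
        contam_frags = fragment_sequence(contam_strain, spec.contaminant_fragment_bp)
        n_pieces = min(
            len(contam_frags), max(1, round(frac * host_bp / spec.contaminant_fragment_bp))
        )
        picks = rng.choice(len(contam_frags), size=n_pieces, replace=False)
        for i in sorted(picks):
            seq_id = f"contam_{contaminant_taxid}_{i}"
            records.append((seq_id, contam_frags[i]))
            label(seq_id, "contaminant", contaminant_taxid)

    elif mode == "chimera":
        if contaminant_taxid is None:
            raise ValueError("chimera mode needs a contaminant_taxid")
        host_strain = _strain_of(refset, host_taxid, rng)
        host_frags = fragment_sequence(host_strain, spec.chimera_host_bp)
        contam_strain = _strain_of(refset, contaminant_taxid, rng)
        contam_frags = fragment_sequence(contam_strain, spec.chimera_contaminant_bp)
        rng.shuffle(contam_frags)
        n = len(host_frags) if n_chimeras is None else min(n_chimeras, len(host_frags))
        sep = "N" * spec.chimera_n_separator if use_n_separator else ""
        for i in range(n):
            contam = contam_frags[i % len(contam_frags)]
            seq_id = f"chimera_{host_taxid}_{contaminant_taxid}_{i}"
            records.append((seq_id, host_frags[i] + sep + contam))
            rows.append(
                (seq_id, "chimera", contaminant_taxid,
                 refset.taxonomy.resolve(contaminant_taxid).division,
                 refset.taxonomy.resolve(contaminant_taxid).kingdom)
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    truth = pd.DataFrame(rows, columns=["seq_id", "role", "taxid", "division", "kingdom"])
    return QuerySet(records=records, truth=truth)
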