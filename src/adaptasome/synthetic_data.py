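"""Synthetic study generator with planted family expansions.

Emulates the data a comparative proteome-annotation survey produces —
overdispersed family copy-number matrices across organisms with correlated
lifestyle labels — with known ground truth, so the contrast-and-select
pipeline is testable end to end without proteome downloads or database
licenses.

Counts are negative-binomial (Poisson-gamma): real family counts are
overdispersed across lineages (whole-genome duplications, lineage-specific
blooms), so a Poisson baseline would be unrealistically tight.  A "planted
expansion" multiplies one family's mean by a fold factor in every organism
carrying a chosen lifestyle label — the ground truth that recovery tests
score against.

Organism lifestyles are drawn from a small set of ecotype bundles of
co-occurring labels (e.g. terrestrial saprotrophs that associate with
plants), so lifestyle groups overlap as they do in real surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_ingest import Database, FamilyCountMatrix, FamilyKey
from .curation import CatalyticSiteSpec
from .ecology import VOCABULARY, EcologyTable

__all__ = [
    "ECOTYPE_BUNDLES",
    "FamilyParams",
    "SyntheticScenario",
    "default_scenario",
    "generate_counts",
    "emit_blast_tab",
    "emit_domtblout",
    "make_curation_fixture",
]

# Ecotype label bundles: realistic co-occurrence patterns (a terrestrial
# saprotroph lives on land and associates with plant litter, an animal
# pathogen with its host, ...).  Organisms are spread over these cyclically.
ECOTYPE_BUNDLES: tuple[frozenset[str], ...] = (
    frozenset({"saprotroph", "living_on_land", "associated_with_plants"}),
    frozenset({"saprotroph", "living_in_water"}),
    frozenset({"pathogen", "associated_with_plants", "living_on_land"}),
    frozenset({"pathogen", "opportunistic_pathogen", "associated_with_animals"}),
    frozenset({"opportunistic_pathogen", "commensal", "associated_with_animals", "living_on_land"}),
    frozenset({"mutualist", "endophyte", "associated_with_plants", "living_on_land"}),
    frozenset({"pathogen", "living_in_water", "associated_with_animals"}),
    frozenset({"mutualist", "associated_with_plants", "living_on_land"}),
)


@dataclass(frozen=True)
class FamilyParams:
    """Negative-binomial baseline of one family: mean mu and dispersion k.

    Variance is mu + mu^2 / k, so small k means strong overdispersion.
    """

    family_id: str
    database: Database
    mu: float
    k: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")

    @property
    def key(self) -> FamilyKey:
        return (str(self.database), self.family_id)


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified simulated study, reproducible from its seed."""

    organisms: tuple[tuple[str, frozenset[str]], ...]  # (organism_id, labels)
    families: tuple[FamilyParams, ...]
    plants: tuple[tuple[str, str, float], ...] = ()  # (family_id, label, fold)
    seed: int = 0

    def __post_init__(self) -> None:
        fam_ids = {f.family_id for f in self.families}
        for fam, label, fold in self.plants:
            if fold < 1:
                raise ValueError(f"planted fold must be >= 1, got {fold}")
            if label not in VOCABULARY:
                raise ValueError(f"planted label {label!r} not in vocabulary")
            if fam not in fam_ids:
                raise ValueError(f"planted family {fam!r} not in scenario")


def _synthetic_families(n_families: int, rng: np.random.Generator) -> tuple[FamilyParams, ...]:
    """Families split across the three databases with heterogeneous baselines."""
    mus = np.exp(rng.uniform(np.log(1.0), np.log(20.0), size=n_families))
    ks = rng.uniform(1.0, 4.0, size=n_families)
    families = []
    for i in range(n_families):
        db = (Database.MEROPS, Database.CAZY, Database.TCDB)[i % 3]
        if db is Database.MEROPS:
            fam = f"X{i:03d}"
        elif db is Database.CAZY:
            fam = f"GH{9000 + i}"
        else:
            fam = f"9.B.{i}"  # synthetic transporter class
        families.append(FamilyParams(fam, db, float(mus[i]), float(ks[i])))
    return tuple(families)


def default_scenario(
    n_organisms: int = 40,
    n_families: int = 200,
    n_planted: int = 0,
    fold: float = 8.0,
    min_group_size: int = 8,
    seed: int = 0,
) -> SyntheticScenario:
    """Build the standard simulated study.

    Organisms cycle through the ecotype bundles; family baselines are drawn
    once from the scenario seed (means log-uniform on [1, 20], dispersions
    uniform on [1, 4]).  ``n_planted`` expansions of the given fold are
    planted on distinct families, on labels whose groups have at least
    ``min_group_size`` carriers, cycling through those labels.
    """
    rng = np.random.default_rng(seed)
    organisms = tuple(
        (f"org{i:03d}", ECOTYPE_BUNDLES[i % len(ECOTYPE_BUNDLES)])
        for i in range(n_organisms)
    )
    families = _synthetic_families(n_families, rng)

    plants: list[tuple[str, str, float]] = []
    if n_planted:
        label_sizes: dict[str, int] = {}
        for _org, labels in organisms:
            for lab in labels:
                label_sizes[lab] = label_sizes.get(lab, 0) + 1
        eligible = sorted(l for l, n in label_sizes.items() if n >= min_group_size)
        if not eligible:
            raise ValueError(
                f"no label reaches group size {min_group_size} with "
                f"{n_organisms} organisms"
            )
        planted_fams = rng.choice(len(families), size=n_planted, replace=False)
        for j, fi in enumerate(sorted(planted_fams)):
            plants.append((families[fi].family_id, eligible[j % len(eligible)], fold))
    return SyntheticScenario(
        organisms=organisms, families=families, plants=tuple(plants), seed=seed
    )


def generate_counts(
    scenario: SyntheticScenario,
) -> tuple[FamilyCountMatrix, EcologyTable, pd.DataFrame]:
    """Draw the count matrix, ecology table and planted-truth table.

    Count for organism o and family f is negative-binomial with mean
    mu_f x product of folds of plants whose label o carries, and dispersion
    k_f.  Deterministic under the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed + 1)  # distinct from builder stream
    org_ids = [org for org, _ in scenario.organisms]
    org_labels = [labels for _, labels in scenario.organisms]

    fold_by_family: dict[str, list[tuple[str, float]]] = {}
    for fam, label, fold in scenario.plants:
        fold_by_family.setdefault(fam, []).append((label, fold))

    counts = np.zeros((len(org_ids), len(scenario.families)), dtype=np.int64)
    for j, fam in enumerate(scenario.families):
        mu = np.full(len(org_ids), fam.mu)
        for label, fold in fold_by_family.get(fam.family_id, ()):
            carriers = np.array([label in labels for labels in org_labels])
            mu[carriers] *= fold
        p = fam.k / (fam.k + mu)
        counts[:, j] = rng.negative_binomial(fam.k, p)

    data = pd.DataFrame(
        counts,
        index=pd.Index(org_ids, name="organism"),
        columns=pd.MultiIndex.from_tuples(
            [f.key for f in scenario.families], names=["database", "family"]
        ),
    )
    matrix = FamilyCountMatrix(data)
    ecology = EcologyTable(entries={org: labels for org, labels in scenario.organisms})
    db_of = {f.family_id: str(f.database) for f in scenario.families}
    truth = pd.DataFrame(
        [
            {"family": fam, "database": db_of[fam], "label": label, "fold": fold}
            for fam, label, fold in scenario.plants
        ],
        columns=["family", "database", "label", "fold"],
    )
    return matrix, ecology, truth


# ---------------------------------------------------------------------------
# raw hit-file emitters (round-trip inverses of the ingest parsers)

_EMIT_EVALUE = "1e-50"  # comfortably below the default 1e-10 cutoff


def _subject_for(family_id: str, database: Database) -> str:
    if database is Database.MEROPS:
        return f"MER:{family_id}.001"
    # TCDB accessions extend the 3-component family to 5 components
    return f"TC:{family_id}.1.1"


def emit_blast_tab(
    row_counts: Mapping[FamilyKey, int],
    organism_id: str,
    database: Database,
) -> str:
    """Emit BLAST outfmt-6 lines realising a count-matrix row for one database.

    For each family with count c, writes c hit lines with distinct synthetic
    protein ids and e-values below the default cutoff, so parse -> filter ->
    assign (any policy) -> count reconstructs the row exactly.
    """
    database = Database(database)
    lines: list[str] = []
    for (db, fam), c in sorted(row_counts.items()):
        if db != str(database):
            continue
        if c < 0:
            raise ValueError(f"negative count for {fam}")
        for j in range(c):
            query = f"{organism_id}|{db}|{fam}|p{j:03d}"
            subject = _subject_for(fam, database)
            lines.append(
                f"{query}\t{subject}\t97.5\t150\t3\t0\t1\t150\t1\t150\t"
                f"{_EMIT_EVALUE}\t250.0\n"
            )
    return "".join(lines)


def emit_domtblout(row_counts: Mapping[FamilyKey, int], organism_id: str) -> str:
    """Emit hmmscan --domtblout text realising a row's CAZy counts."""
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain -------------\n"
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target\n"
        "#------------------- ---------- ----- -------------------- "
        "---------- ----- --------- ------ ----- --- --- --------- "
        "--------- ------ ----- ----- ----- ----- ----- ----- ----- ---- "
        "---------------------\n"
    )
    lines = [header]
    for (db, fam), c in sorted(row_counts.items()):
        if db != str(Database.CAZY):
            continue
        if c < 0:
            raise ValueError(f"negative count for {fam}")
        for j in range(c):
            query = f"{organism_id}|{db}|{fam}|p{j:03d}"
            lines.append(
                f"{fam}.hmm - 200 {query} - 350 {_EMIT_EVALUE} 180.0 0.1 "
                f"1 1 {_EMIT_EVALUE} {_EMIT_EVALUE} 180.0 0.1 "
                f"1 200 10 210 5 215 0.95 -\n"
            )
    return "".join(lines)


# ---------------------------------------------------------------------------
# curation fixtures

_REF_SEQ = (
    "MKTAYLLVAGSDTWQNRHEFIKDPSGLMVNACEQRTYHGIDLPKSAVWFETNQRGCLMAK"
)
_CATALYTIC = {12: "S", 25: "H", 40: "D"}  # Ser/His/Asp triad, 1-based positions
_CONSERVED_REGION = (30, 50)
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# residues outside every same-chemistry group of the catalytic triad
_POISON = "GPWF"


def make_curation_fixture(
    n_pass: int,
    n_fail_gap: int,
    n_fail_subst: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], CatalyticSiteSpec, pd.DataFrame]:
    """Build an alignment with engineered curation failures and its truth.

    The reference carries a Ser/His/Asp catalytic triad and one conserved
    region.  Passing sequences mutate only benign positions; gap failures
    put a gap on a catalytic column; substitution failures replace a
    catalytic residue with a chemically incompatible one (invalid under both
    strict and relaxed policies).
    """
    if min(n_pass, n_fail_gap, n_fail_subst) < 0:
        raise ValueError("sequence counts must be >= 0")
    rng = np.random.default_rng(seed)
    ref = list(_REF_SEQ)
    for pos, res in _CATALYTIC.items():
        ref[pos - 1] = res
    ref_seq = "".join(ref)
    catalytic_cols = set(_CATALYTIC)

    def benign_mutant() -> str:
        seq = list(ref_seq)
        n_mut = int(rng.integers(2, 7))
        mutable = [
            i for i in range(1, len(ref_seq) + 1) if i not in catalytic_cols
        ]
        for pos in rng.choice(mutable, size=n_mut, replace=False):
            seq[pos - 1] = _RESIDUES[int(rng.integers(len(_RESIDUES)))]
        return "".join(seq)

    rows: list[tuple[str, str]] = [("REF", ref_seq)]
    truth_rows = [{"sequence_id": "REF", "status": "pass", "reason": ""}]
    for i in range(n_pass):
        rows.append((f"pass_{i:02d}", benign_mutant()))
        truth_rows.append({"sequence_id": f"pass_{i:02d}", "status": "pass", "reason": ""})
    for i in range(n_fail_gap):
        seq = list(benign_mutant())
        pos = sorted(catalytic_cols)[int(rng.integers(len(catalytic_cols)))]
        seq[pos - 1] = "-"
        rows.append((f"gapfail_{i:02d}", "".join(seq)))
        truth_rows.append(
            {"sequence_id": f"gapfail_{i:02d}", "status": "fail", "reason": "catalytic_gap"}
        )
    for i in range(n_fail_subst):
        seq = list(benign_mutant())
        pos = sorted(catalytic_cols)[int(rng.integers(len(catalytic_cols)))]
        seq[pos - 1] = _POISON[int(rng.integers(len(_POISON)))]
        rows.append((f"substfail_{i:02d}", "".join(seq)))
        truth_rows.append(
            {
                "sequence_id": f"substfail_{i:02d}",
                "status": "fail",
                "reason": "invalid_substitution",
            }
        )
    spec = CatalyticSiteSpec(
        family_id="SYN1",
        reference_id="REF",
        catalytic_positions=tuple(sorted(_CATALYTIC)),
        allowed_residues={p: frozenset({r}) for p, r in _CATALYTIC.items()},
        conserved_regions=(_CONSERVED_REGION,),
    )
    truth = pd.DataFrame(truth_rows, columns=["sequence_id", "status", "reason"])
    return rows, spec, truth
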