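"""Germination-trial data model and delimited-text I/O.

The unit of observation is one Petri dish: for a given species, treatment
(C = control, H = heat pulse, S = smoke, HS = heat + smoke) and replicate,
``germinated`` seeds (G) out of ``viable`` seeds (V) out of ``sown`` seeds.
Experiment 1 species receive the full 2x2 factorial {C, H, S, HS};
experiment 2 species receive only {C, HS}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

TREATMENTS_EXP1 = ("C", "H", "S", "HS")
TREATMENTS_EXP2 = ("C", "HS")
VALID_TREATMENTS = frozenset(TREATMENTS_EXP1)

COLUMNS = (
    "species_id",
    "experiment",
    "treatment",
    "replicate",
    "sown",
    "viable",
    "germinated",
)

TRAIT_COLUMNS = ("species_id", "seed_bank", "seed_morphology", "persistence")
SEED_BANKS = frozenset({"canopy", "soil"})
SEED_MORPHOLOGIES = frozenset({"nutlet", "winged"})
PERSISTENCE = frozenset({"resprouter", "non-resprouter"})


class ValidationError(ValueError):
    """Raised when a table violates the germination data model."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class GerminationObservation:
    """One Petri dish: G germinated out of V viable out of ``sown`` seeds."""

    species_id: str
    experiment: int
    treatment: str
    replicate: int
    sown: int
    viable: int
    germinated: int

    def __post_init__(self):
        errs = _check_row(self.__dict__)
        if errs:
            raise ValidationError(errs)

    @property
    def fraction(self) -> float:
        """Germination relative to viable seeds, G/V."""
        return germination_fraction(self)


@dataclass(frozen=True)
class SpeciesTraits:
    """Life-history and seed traits used in the prevalence comparisons."""

    species_id: str
    seed_bank: str        # canopy (serotinous) or soil (geosporous)
    seed_morphology: str  # nutlet or winged achene
    persistence: str      # resprouter or non-resprouter

    def __post_init__(self):
        errs = []
        if self.seed_bank not in SEED_BANKS:
            errs.append(f"{self.species_id}: unknown seed_bank {self.seed_bank!r}")
        if self.seed_morphology not in SEED_MORPHOLOGIES:
            errs.append(
                f"{self.species_id}: unknown seed_morphology {self.seed_morphology!r}"
            )
        if self.persistence not in PERSISTENCE:
            errs.append(f"{self.species_id}: unknown persistence {self.persistence!r}")
        if errs:
            raise ValidationError(errs)


def _check_row(d: dict) -> list[str]:
    errs = []
    if d["experiment"] not in (1, 2):
        errs.append(f"experiment must be 1 or 2, got {d['experiment']!r}")
    if d["treatment"] not in VALID_TREATMENTS:
        errs.append(f"unknown treatment {d['treatment']!r}")
    elif d["experiment"] == 2 and d["treatment"] not in TREATMENTS_EXP2:
        errs.append(
            f"treatment {d['treatment']!r} not applied in experiment 2 (only C, HS)"
        )
    if d["replicate"] < 1:
        errs.append(f"replicate must be >= 1, got {d['replicate']}")
    for k in ("sown", "viable", "germinated"):
        if d[k] < 0:
            errs.append(f"{k} must be non-negative, got {d[k]}")
    if d["germinated"] > d["viable"]:
        errs.append(
            f"germinated exceeds viable ({d['germinated']} > {d['viable']})"
        )
    if d["viable"] > d["sown"]:
        errs.append(f"viable exceeds sown ({d['viable']} > {d['sown']})")
    return errs


def germination_fraction(obs: GerminationObservation) -> float:
    """G/V: germination relative to viable seeds in the dish.

    Raises :class:`ValidationError` when no viable seeds were present.
    """
    if obs.viable == 0:
        raise ValidationError(
            [f"{obs.species_id} {obs.treatment} rep {obs.replicate}: "
             "germination fraction undefined for viable=0"]
        )
    return obs.germinated / obs.viable


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_germination_table(
    path: str | Path, delimiter: str = ","
) -> list[GerminationObservation]:
    """Read a dish-level germination table from delimited text.

    The header must name the seven canonical columns (any order). Rows that
    violate the count invariants 0 <= G <= V <= sown are reported together in
    a single :class:`ValidationError`, each message naming the offending row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing column(s): {', '.join(missing)}"])

    errors: list[str] = []
    out: list[GerminationObservation] = []
    for idx, row in df.iterrows():
        label = f"row {idx + 2}"  # header is line 1
        vals = {}
        ok = True
        for col in ("experiment", "replicate", "sown", "viable", "germinated"):
            try:
                vals[col] = int(str(row[col]).strip())
            except (TypeError, ValueError):
                errors.append(f"{label}: non-integer {col} {row[col]!r}")
                ok = False
        if not ok:
            continue
        try:
            out.append(
                GerminationObservation(
                    species_id=str(row["species_id"]).strip(),
                    treatment=str(row["treatment"]).strip(),
                    **vals,
                )
            )
        except ValidationError as e:
            errors.extend(f"{label}: {m}" for m in e.errors)
    if errors:
        raise ValidationError(errors)
    return out


def write_germination_table(
    obs: Iterable[GerminationObservation], path: str | Path, delimiter: str = ","
) -> None:
    """Write observations in the canonical column order (round-trip safe)."""
    df = observations_to_frame(obs)
    df.to_csv(path, sep=delimiter, index=False)


def observations_to_frame(obs: Iterable[GerminationObservation]) -> pd.DataFrame:
    rows = [[getattr(o, c) for c in COLUMNS] for o in obs]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def read_trait_table(path: str | Path, delimiter: str = ",") -> list[SpeciesTraits]:
    """Read the per-species trait table (one row per species)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing column(s): {', '.join(missing)}"])
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError([f"duplicate species: {', '.join(dups)}"])
    return [
        SpeciesTraits(*(str(row[c]).strip() for c in TRAIT_COLUMNS))
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# design validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSummary:
    """Per-species summary of the factorial design actually present."""

    species_id: str
    experiment: int
    treatments: tuple[str, ...]
    replicates_per_treatment: dict[str, int]
    total_viable: int
    complete: bool
    problems: tuple[str, ...]


def validate_design(obs: Sequence[GerminationObservation]) -> dict[str, DesignSummary]:
    """Check each species' design against its experiment's factorial.

    Experiment 1 requires all of {C, H, S, HS}; experiment 2 requires {C, HS}.
    Replicates must be unique within (species, treatment). Species mixing
    experiment codes raise immediately.
    """
    if not obs:
        raise ValidationError(["empty observation collection"])
    by_species: dict[str, list[GerminationObservation]] = {}
    for o in obs:
        by_species.setdefault(o.species_id, []).append(o)

    out: dict[str, DesignSummary] = {}
    for sp, rows in by_species.items():
        exps = sorted({o.experiment for o in rows})
        if len(exps) > 1:
            raise ValidationError([f"{sp}: mixes experiment codes {exps}"])
        exp = exps[0]
        expected = TREATMENTS_EXP1 if exp == 1 else TREATMENTS_EXP2
        problems: list[str] = []
        reps: dict[str, list[int]] = {}
        for o in rows:
            reps.setdefault(o.treatment, []).append(o.replicate)
        for trt, rlist in reps.items():
            if len(set(rlist)) != len(rlist):
                problems.append(f"duplicate replicate numbers in treatment {trt}")
        present = tuple(t for t in TREATMENTS_EXP1 if t in reps)
        missing = [t for t in expected if t not in reps]
        if missing:
            problems.append(f"missing treatment(s): {', '.join(missing)}")
        out[sp] = DesignSummary(
            species_id=sp,
            experiment=exp,
            treatments=present,
            replicates_per_treatment={t: len(r) for t, r in sorted(reps.items())},
            total_viable=sum(o.viable for o in rows),
            complete=not problems,
            problems=tuple(problems),
        )
    return out


def group_by_species(
    obs: Iterable[GerminationObservation],
) -> dict[str, list[GerminationObservation]]:
    out: dict[str, list[GerminationObservation]] = {}
    for o in obs:
        out.setdefault(o.species_id, []).append(o)
    return out
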