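"""End-to-end study pipeline: fit per-species models, apply the HDI+ROPE
decision rule, assign syndromes, cross-tabulate against life-history traits,
compare prevalences, and (optionally) test phylogenetic signal.

Per species the stages are: detect complete separation (choose the prior) ->
fit the binomial GLM -> posterior-predictive dispersion check -> refit as a
GLMM with a dish random effect when the check fails -> classify control
germination and cue effects -> assign the FD/FE/FI/FU syndrome.  A failure
in one species is recorded and the pipeline continues with the rest.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import decision, io, model, phylo
from .contingency import ContingencyTable2x2, PropCompareResult, bayes_prop_compare
from .decision import (
    DEFAULT_CONTROL_ROPE,
    DEFAULT_EFFECT_ROPE,
    ControlClassification,
    EffectClassification,
    Interval,
    SyndromeCall,
)
from .io import GerminationObservation, SpeciesTraits
from .model import ModelSpec, PosteriorDraws, SamplerConfig

__all__ = [
    "PipelineConfig",
    "SpeciesResult",
    "StudyReport",
    "classify_species",
    "run_pipeline",
    "cross_tabulate",
    "binary_response_trait",
    "write_report",
]

DIRECT_CUE_CONTRASTS = {1: ("H-C", "S-C", "HS-C"), 2: ("HS-C",)}


@dataclass(frozen=True)
class PipelineConfig:
    germination_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    delimiter: str = ","
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(seed=1))
    effect_rope: tuple[float, float] = (
        DEFAULT_EFFECT_ROPE.lower,
        DEFAULT_EFFECT_ROPE.upper,
    )
    control_rope: tuple[float, float] = (
        DEFAULT_CONTROL_ROPE.lower,
        DEFAULT_CONTROL_ROPE.upper,
    )
    tau: float = 0.85
    ppc_band: tuple[float, float] = (0.05, 0.95)
    contingency_draws: int = 200_000
    contingency_seed: int = 1
    n_permutations: int = 999
    permutation_seed: int = 1
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sampler = SamplerConfig(**raw.pop("sampler", {}))
        for key in ("effect_rope", "control_rope", "ppc_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sampler=sampler, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class SpeciesResult:
    species_id: str
    syndrome: SyndromeCall
    control: ControlClassification
    effects: tuple[EffectClassification, ...]
    fit: PosteriorDraws
    glm_fit: PosteriorDraws | None  # pre-refit GLM when a GLMM refit happened
    prior_family: str
    overdispersed: bool
    bayesian_p: float
    seed: int


@dataclass
class StudyReport:
    species: dict[str, SpeciesResult]
    errors: dict[str, str]
    contingency: dict[str, PropCompareResult]
    phylo_signal: dict[str, phylo.KResult]
    provenance: dict


def _species_seed(base: int, species_id: str) -> int:
    return (base * 1_000_003 + zlib.crc32(species_id.encode())) % (2**31 - 1)


def classify_species(
    obs: Sequence[GerminationObservation],
    sampler: SamplerConfig,
    effect_rope: Interval = DEFAULT_EFFECT_ROPE,
    control_rope: Interval = DEFAULT_CONTROL_ROPE,
    tau: float = 0.85,
    ppc_band: tuple[float, float] = (0.05, 0.95),
) -> SpeciesResult:
    """Fit, diagnose, (re)fit and classify one species.

    Separated cells trigger Student-t priors up front; a dispersion
    posterior-predictive p outside ``ppc_band`` triggers a GLMM refit with a
    dish-level random effect.  Both fits are retained when a refit happens.
    """
    X, G, V, exp, row_trts = model.build_design(obs)
    separated = model.detect_separation(G, V, row_trts)
    prior = "student_t" if separated else "flat-normal"
    spec = ModelSpec(experiment=exp, prior_family=prior)

    fit = model.fit_model(X, (G, V), spec, sampler, row_treatments=row_trts)
    glm_fit = None
    overdispersed = False
    if fit.bayesian_p is not None and not (
        ppc_band[0] < fit.bayesian_p < ppc_band[1]
    ):
        glm_fit = fit
        fit = model.fit_overdispersed(
            X, (G, V), spec, sampler, row_treatments=row_trts
        )
        overdispersed = True

    pi = model.treatment_probabilities(fit)
    control = decision.classify_control(pi["C"], rope=control_rope)
    contrasts = model.effect_draws(fit, DIRECT_CUE_CONTRASTS[exp])
    effects = tuple(
        decision.rope_classify(d, rope=effect_rope, name=name)
        for name, d in contrasts.items()
    )
    call = decision.assign_syndrome(control, effects, pi, tau=tau)
    return SpeciesResult(
        species_id=obs[0].species_id,
        syndrome=call,
        control=control,
        effects=effects,
        fit=fit,
        glm_fit=glm_fit,
        prior_family=prior,
        overdispersed=overdispersed,
        bayesian_p=fit.bayesian_p,
        seed=sampler.seed,
    )


# ---------------------------------------------------------------------------
# trait cross-tabulation
# ---------------------------------------------------------------------------

def _cue_status(result: SpeciesResult, cue: str) -> str | None:
    """'effect' / 'no_effect' / None (uncertain or not measured) per species.

    cue in {'fire', 'heat', 'smoke'}.  A promotive effect means verdict
    non_trivial with positive mode; fire = heat and/or smoke (for
    experiment 2 species the combined cue stands in).  Uncertain statuses
    return None and are excluded from the tables.
    """
    by_name = {e.name: e for e in result.effects}
    if cue == "heat":
        wanted = ["H-C"]
    elif cue == "smoke":
        wanted = ["S-C"]
    else:
        wanted = [n for n in ("H-C", "S-C", "HS-C") if n in by_name]
    effs = [by_name[n] for n in wanted if n in by_name]
    if not effs:
        return None
    if any(e.verdict == "non_trivial" and e.mode > 0 for e in effs):
        return "effect"
    if all(e.verdict == "trivial" for e in effs):
        return "no_effect"
    return None


_TRAIT_GROUPS = {
    "seed_bank": ("soil", "canopy"),
    "persistence": ("non-resprouter", "resprouter"),
    "seed_morphology": ("nutlet", "winged"),
}

DEFAULT_COMPARISONS = (
    ("fire", "seed_bank"),
    ("heat", "seed_bank"),
    ("smoke", "seed_bank"),
    ("fire", "persistence"),
    ("fire", "seed_morphology"),
)


def cross_tabulate(
    results: Mapping[str, SpeciesResult],
    traits: Sequence[SpeciesTraits],
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    subset: Mapping[str, str] | None = None,
) -> tuple[dict[str, ContingencyTable2x2], list[str]]:
    """Build cue-by-trait 2x2 tables from syndrome/effect calls.

    Species with an uncertain cue status are excluded from that cue's
    tables; species missing trait data are listed in the returned exclusion
    list.  ``subset`` restricts species by trait value (e.g. nutlet-bearing
    only).
    """
    trait_by_sp = {t.species_id: t for t in traits}
    missing = sorted(set(results) - set(trait_by_sp))
    tables: dict[str, ContingencyTable2x2] = {}
    for cue, trait_name in comparisons:
        groups = _TRAIT_GROUPS[trait_name]
        succ = {g: 0 for g in groups}
        tot = {g: 0 for g in groups}
        for sp, res in results.items():
            tr = trait_by_sp.get(sp)
            if tr is None:
                continue
            if subset and any(
                getattr(tr, k) != v for k, v in subset.items()
            ):
                continue
            status = _cue_status(res, cue)
            if status is None:
                continue
            g = getattr(tr, trait_name)
            tot[g] += 1
            if status == "effect":
                succ[g] += 1
        if all(tot[g] > 0 for g in groups):
            tables[f"{cue}_vs_{trait_name}"] = ContingencyTable2x2(
                group_labels=groups,
                successes=(succ[groups[0]], succ[groups[1]]),
                totals=(tot[groups[0]], tot[groups[1]]),
            )
    return tables, missing


def binary_response_trait(
    results: Mapping[str, SpeciesResult],
    cue: str,
    include_uncertain_as_zero: bool = False,
) -> dict[str, int]:
    """0/1 response-to-cue trait vector from the effect classifications.

    Uncertain species are excluded by default (matching the contingency
    tables) or coded 0 when ``include_uncertain_as_zero`` is set.
    """
    out = {}
    for sp, res in results.items():
        status = _cue_status(res, cue)
        if status is None:
            if include_uncertain_as_zero:
                out[sp] = 0
            continue
        out[sp] = 1 if status == "effect" else 0
    return out


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    observations: Sequence[GerminationObservation] | None = None,
    traits: Sequence[SpeciesTraits] | None = None,
    tree: phylo.Tree | None = None,
    extra_tables: Mapping[str, ContingencyTable2x2] | None = None,
) -> StudyReport:
    """Run the full analysis and assemble a report.

    Inputs may come from the config's file paths or be passed in memory.
    ``extra_tables`` lets printed 2x2 count tables enter the prevalence
    comparison directly.  Deterministic under fixed config seeds; a failing
    species is recorded in ``report.errors`` without stopping the rest.
    """
    if observations is None and config.germination_path:
        observations = io.read_germination_table(
            config.germination_path, config.delimiter
        )
    if traits is None and config.traits_path:
        traits = io.read_trait_table(config.traits_path, config.delimiter)
    if tree is None and config.tree_path:
        tree = phylo.parse_newick(Path(config.tree_path).read_text())

    effect_rope = Interval(*config.effect_rope, mass=1.0)
    control_rope = Interval(*config.control_rope, mass=1.0)

    results: dict[str, SpeciesResult] = {}
    errors: dict[str, str] = {}
    if observations:
        by_species = io.group_by_species(observations)
        for sp in sorted(by_species):
            cfg = SamplerConfig(
                chains=config.sampler.chains,
                iterations=config.sampler.iterations,
                burn_in=config.sampler.burn_in,
                thinning=config.sampler.thinning,
                seed=_species_seed(config.sampler.seed, sp),
            )
            try:
                results[sp] = classify_species(
                    by_species[sp],
                    cfg,
                    effect_rope=effect_rope,
                    control_rope=control_rope,
                    tau=config.tau,
                    ppc_band=config.ppc_band,
                )
            except Exception as e:  # keep going; record the failure
                errors[sp] = f"{type(e).__name__}: {e}"

    contingency: dict[str, PropCompareResult] = {}
    tables: dict[str, ContingencyTable2x2] = {}
    if traits and results:
        tables, _missing = cross_tabulate(results, traits)
    if extra_tables:
        tables.update(extra_tables)
    for i, (name, tab) in enumerate(sorted(tables.items())):
        contingency[name] = bayes_prop_compare(
            tab, config.contingency_draws, config.contingency_seed + i
        )

    physig: dict[str, phylo.KResult] = {}
    if tree is not None and results:
        for cue in ("heat", "smoke"):
            trait = binary_response_trait(results, cue)
            labels = set(phylo.tip_labels(tree))
            trait = {k: v for k, v in trait.items() if k in labels}
            if len(trait) >= 3 and len(set(trait.values())) > 1:
                sub = tree.extract_tree_with_taxa_labels(list(trait))
                physig[cue] = phylo.k_permutation_test(
                    sub,
                    trait,
                    n_perm=config.n_permutations,
                    seed=config.permutation_seed,
                )

    cfg_dict = config.to_dict()
    provenance = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "species_seeds": {sp: r.seed for sp, r in results.items()},
        "contingency_seed": config.contingency_seed,
        "permutation_seed": config.permutation_seed,
    }
    return StudyReport(
        species=results,
        errors=errors,
        contingency=contingency,
        phylo_signal=physig,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------

def _interval_dict(iv: Interval) -> dict:
    return {"lower": round(iv.lower, 6), "upper": round(iv.upper, 6)}


def report_to_dict(report: StudyReport) -> dict:
    species = {}
    for sp, r in sorted(report.species.items()):
        species[sp] = {
            "syndrome": r.syndrome.label,
            "annotations": list(r.syndrome.annotations),
            "control": {
                "mode": round(r.control.mode, 4),
                "hdi": _interval_dict(r.control.hdi),
                "verdict": r.control.verdict,
                "p_ge_50": round(r.control.p_ge_50, 4),
            },
            "effects": [
                {
                    "name": e.name,
                    "mode": round(e.mode, 4),
                    "hdi": _interval_dict(e.hdi),
                    "verdict": e.verdict,
                    "mass_outside_rope": round(e.mass_outside_rope, 4),
                    "hdi_mass_outside_rope": round(e.hdi_mass_outside_rope, 4),
                }
                for e in r.effects
            ],
            "diagnostics": {
                "rhat": {k: round(v, 4) for k, v in r.fit.rhat.items()},
                "ess": {k: round(v, 1) for k, v in r.fit.ess.items()},
                "bayesian_p": round(r.bayesian_p, 4),
                "converged": r.fit.converged,
                "prior_family": r.prior_family,
                "overdispersed": r.overdispersed,
                "warnings": list(r.fit.warnings),
            },
        }
    contingency = {
        name: {
            "groups": list(res.table.group_labels),
            "successes": list(res.table.successes),
            "totals": list(res.table.totals),
            "freq_mode": [round(m, 4) for m in res.freq_mode],
            "freq_hdi": [_interval_dict(h) for h in res.freq_hdi],
            "diff_mode": round(res.diff_mode, 4),
            "diff_hdi": _interval_dict(res.diff_hdi),
            "p_direction": round(res.p_direction, 4),
            "n_draws": res.n_draws,
        }
        for name, res in sorted(report.contingency.items())
    }
    physig = {
        cue: {
            "K": round(r.K, 4),
            "p_value": round(r.p_value, 4),
            "n_permutations": r.n_permutations,
            "ultrametric": r.ultrametric,
        }
        for cue, r in sorted(report.phylo_signal.items())
    }
    return {
        "species": species,
        "errors": dict(sorted(report.errors.items())),
        "contingency": contingency,
        "phylo_signal": physig,
        "provenance": report.provenance,
    }


def species_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for sp, r in sorted(report.species.items()):
        rows.append(
            {
                "species_id": sp,
                "syndrome": r.syndrome.label,
                "annotations": ";".join(r.syndrome.annotations),
                "control_mode": round(r.control.mode, 4),
                "control_hdi_lower": round(r.control.hdi.lower, 4),
                "control_hdi_upper": round(r.control.hdi.upper, 4),
                "p_control_ge_50": round(r.control.p_ge_50, 4),
                "prior_family": r.prior_family,
                "overdispersed": r.overdispersed,
                "bayesian_p": round(r.bayesian_p, 4),
                "max_rhat": round(max(r.fit.rhat.values()), 4),
                "min_ess": round(min(r.fit.ess.values()), 1),
            }
        )
    return pd.DataFrame(rows)


def effects_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for sp, r in sorted(report.species.items()):
        for e in r.effects:
            rows.append(
                {
                    "species_id": sp,
                    "contrast": e.name,
                    "mode": round(e.mode, 4),
                    "hdi_lower": round(e.hdi.lower, 4),
                    "hdi_upper": round(e.hdi.upper, 4),
                    "verdict": e.verdict,
                    "mass_outside_rope": round(e.mass_outside_rope, 4),
                    "hdi_mass_outside_rope": round(e.hdi_mass_outside_rope, 4),
                }
            )
    return pd.DataFrame(rows)


def write_report(
    report: StudyReport,
    output_dir: str | Path,
    formats: Sequence[str] = ("csv", "json"),
) -> list[Path]:
    """Write species/effects CSVs, a JSON summary and a plain-text log.

    Output is byte-stable for a given report (sorted keys, fixed rounding),
    so regenerating under an identical config reproduces identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = out / "species.csv"
        species_frame(report).to_csv(p, index=False)
        written.append(p)
        p = out / "effects.csv"
        effects_frame(report).to_csv(p, index=False)
        written.append(p)
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))
        written.append(p)
    log = out / "run.log"
    lines = [
        f"species analysed: {len(report.species)}",
        f"species failed: {len(report.errors)}",
        f"contingency comparisons: {len(report.contingency)}",
        f"phylogenetic signal tests: {len(report.phylo_signal)}",
        f"config hash: {report.provenance['config_hash']}",
    ]
    for sp, msg in sorted(report.errors.items()):
        lines.append(f"ERROR {sp}: {msg}")
    log.write_text("\n".join(lines) + "\n")
    written.append(log)
    return written
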