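"""Built-in intervention catalogue and its serialization.

Encodes the evaluated primary-prevention interventions with their
trial-derived effect sizes (mean and standard error), 2008 AUD annual
costs and delivery modes: blood-pressure-lowering drug classes, aspirin,
statins (at the Australian price and the far lower New Zealand price),
phytosterol-enriched margarine, dietary advice, an intensive lifestyle
program, a community heart health program, mandatory and voluntary limits
on salt in processed foods, and the current-practice blood-pressure- and
cholesterol-lowering therapy mixes.

Sodium effects are stored in mmol/day.  Drug and program costs are split
government/patient with documented default shares (the printed table
reports totals only; parenthesised values there are standard errors).
"""

from __future__ import annotations

from dataclasses import asdict, replace

import yaml

from .errors import ConfigurationError
from .interventions import (
    AdherenceModel,
    CostSchedule,
    EffectSpec,
    FULL_ADHERENCE,
    Intervention,
    ParamUncertainty,
    TARGETABLE_BANDS,
)

#: Government share of drug costs (PBS subsidy net of patient co-payments).
DRUG_GOV_SHARE = 0.8


def _drug_cost(annual: float) -> CostSchedule:
    gov = annual * DRUG_GOV_SHARE
    return CostSchedule(year1_gov=gov, year1_patient=annual - gov)


def _rr(mean: float, se: float) -> ParamUncertainty:
    return ParamUncertainty(mean=mean, se=se, family="lognormal")


def _pct(mean: float, se: float) -> ParamUncertainty:
    return ParamUncertainty(mean=mean, se=se, family="normal")


def _cost(mean: float, se: float) -> ParamUncertainty:
    return ParamUncertainty(mean=mean, se=se, family="gamma")


def builtin_intervention_library() -> list[Intervention]:
    """All interventions of the built-in catalogue with printed means and
    standard errors."""
    lib = [
        Intervention(
            name="Thiazide diuretic", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.86, rr_stroke=0.62),
            costs=_drug_cost(71.0),
            uncertainty={"rr_ihd": _rr(0.86, 0.06),
                         "rr_stroke": _rr(0.62, 0.05)}),
        Intervention(
            name="Beta-blocker", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.89, rr_stroke=0.83),
            costs=_drug_cost(106.0),
            uncertainty={"rr_ihd": _rr(0.89, 0.06),
                         "rr_stroke": _rr(0.83, 0.07)}),
        Intervention(
            name="Calcium channel blocker", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.85, rr_stroke=0.66),
            costs=_drug_cost(218.0),
            uncertainty={"rr_ihd": _rr(0.85, 0.04),
                         "rr_stroke": _rr(0.66, 0.04)}),
        Intervention(
            name="ACE inhibitor", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.83, rr_stroke=0.78),
            costs=_drug_cost(212.0),
            uncertainty={"rr_ihd": _rr(0.83, 0.03),
                         "rr_stroke": _rr(0.78, 0.07)}),
        Intervention(
            name="Aspirin", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.82, rr_stroke_isch=0.86,
                              rr_stroke_haem=1.32, rr_gi_bleed=1.54),
            costs=_drug_cost(40.0),
            uncertainty={"rr_ihd": _rr(0.82, 0.04),
                         "rr_stroke_isch": _rr(0.86, 0.07),
                         "rr_stroke_haem": _rr(1.32, 0.19),
                         "rr_gi_bleed": _rr(1.54, 0.13)}),
        Intervention(
            name="Statin", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.70, rr_stroke=0.81),
            costs=_drug_cost(687.0),
            uncertainty={"rr_ihd": _rr(0.70, 0.05),
                         "rr_stroke": _rr(0.81, 0.06)},
            metadata={"cost_scenarios": {"australia": 687.0, "nz": 19.0}}),
        Intervention(
            name="Phytosterol margarine", delivery="primary_care",
            effect=EffectSpec(tc_pct=7.5),
            # margarine is bought by the patient at the supermarket
            costs=CostSchedule(year1_gov=0.0, year1_patient=258.0),
            uncertainty={"tc_pct": _pct(7.5, 1.9),
                         "cost_year1": _cost(258.0, 38.0),
                         "cost_subsequent": _cost(258.0, 38.0)}),
        Intervention(
            name="Dietary advice", delivery="primary_care",
            effect=EffectSpec(sbp_pct=1.6, tc_pct=3.1),
            costs=CostSchedule(year1_gov=132.0, subsequent_gov=86.0),
            uncertainty={"sbp_pct": _pct(1.6, 0.4),
                         "tc_pct": _pct(3.1, 1.2),
                         "cost_year1": _cost(132.0, 213.0),
                         "cost_subsequent": _cost(86.0, 39.0)}),
        Intervention(
            name="Lifestyle program", delivery="primary_care",
            effect=EffectSpec(sbp_pct=2.6, tc_pct=3.3),
            costs=CostSchedule(year1_gov=257.0, subsequent_gov=172.0),
            uncertainty={"sbp_pct": _pct(2.6, 0.5),
                         "tc_pct": _pct(3.3, 0.6),
                         "cost_year1": _cost(257.0, 152.0),
                         "cost_subsequent": _cost(172.0, 58.0)}),
        Intervention(
            name="Community heart health program", delivery="population_wide",
            effect=EffectSpec(sbp_pct=2.5, tc_pct=-0.51),
            costs=CostSchedule(year1_gov=2.37, subsequent_gov=1.60),
            adherence=FULL_ADHERENCE,
            uncertainty={"sbp_pct": _pct(2.5, 0.7),
                         "tc_pct": _pct(-0.51, 0.6),
                         "cost_year1": _cost(2.37, 0.47),
                         "cost_subsequent": _cost(1.60, 0.32)}),
        Intervention(
            name="Mandatory salt reduction", delivery="population_wide",
            effect=EffectSpec(sodium_by_sex={"male": 10.6, "female": 7.3}),
            costs=CostSchedule(year1_gov=0.81),
            adherence=FULL_ADHERENCE,
            uncertainty={"sodium_male": _pct(10.6, 0.74),
                         "sodium_female": _pct(7.3, 0.53),
                         "cost_year1": _cost(0.81, 0.08),
                         "cost_subsequent": _cost(0.81, 0.08)}),
        Intervention(
            name="Voluntary salt reduction", delivery="population_wide",
            effect=EffectSpec(sodium_by_sex={"male": 0.50, "female": 0.34}),
            costs=CostSchedule(year1_gov=0.49),
            adherence=FULL_ADHERENCE,
            uncertainty={"sodium_male": _pct(0.50, 0.03),
                         "sodium_female": _pct(0.34, 0.02),
                         "cost_year1": _cost(0.49, 0.05),
                         "cost_subsequent": _cost(0.49, 0.05)},
            metadata={"current_practice": True}),
        Intervention(
            name="Lipid-lowering (current practice)", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.70, rr_stroke=0.81),
            costs=_drug_cost(683.0),
            uncertainty={"rr_ihd": _rr(0.70, 0.05),
                         "rr_stroke": _rr(0.81, 0.06)},
            metadata={"current_practice": True}),
        Intervention(
            name="BP-lowering (current practice)", delivery="primary_care",
            effect=EffectSpec(rr_ihd=0.85, rr_stroke=0.70),
            costs=_drug_cost(170.0),
            uncertainty={"rr_ihd": _rr(0.85, 0.04),
                         "rr_stroke": _rr(0.70, 0.05)},
            metadata={"current_practice": True}),
    ]
    return lib


def library_by_name() -> dict[str, Intervention]:
    return {iv.name: iv for iv in builtin_intervention_library()}


def statin_nz_variant(statin: Intervention) -> Intervention:
    """The statin at the New Zealand price scenario (annual cost $19
    instead of $687); effects unchanged."""
    scenarios = statin.metadata.get("cost_scenarios", {})
    nz = float(scenarios.get("nz", 19.0))
    return replace(statin, costs=_drug_cost(nz),
                   metadata={**statin.metadata, "price_scenario": "nz"})


# ---------------------------------------------------------------------------
# Serialization (structured text, mirrors the catalogue columns)
# ---------------------------------------------------------------------------

def intervention_to_dict(iv: Intervention) -> dict:
    d = asdict(iv)
    d["uncertainty"] = {k: asdict(u) for k, u in iv.uncertainty.items()}
    return d


def intervention_from_dict(d: dict) -> Intervention:
    try:
        effect = EffectSpec(**d["effect"])
        costs = CostSchedule(**d["costs"])
        adherence = AdherenceModel(**d.get("adherence", {}))
        uncertainty = {k: ParamUncertainty(**u)
                       for k, u in d.get("uncertainty", {}).items()}
        return Intervention(
            name=d["name"], delivery=d["delivery"], effect=effect,
            costs=costs, target_bands=tuple(
                d.get("target_bands", TARGETABLE_BANDS)),
            adherence=adherence, uncertainty=uncertainty,
            effectiveness_scale=d.get("effectiveness_scale", 1.0),
            metadata=d.get("metadata", {}))
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(
            f"intervention record {d.get('name', '?')!r}: {exc}") from exc


def dump_library(interventions: list[Intervention], path) -> None:
    """Write an intervention library as YAML."""
    payload = {"schema": "cvdcea/interventions/v1",
               "interventions": [intervention_to_dict(iv)
                                 for iv in interventions]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_library(path) -> list[Intervention]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "interventions" not in payload:
        raise ConfigurationError(
            f"{path}: not an intervention library file")
    return [intervention_from_dict(d) for d in payload["interventions"]]
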