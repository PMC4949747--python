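"""Canned study designs for the simulation twin of the assay validation.

The validation twin mirrors how a targeted NAPE assay is validated on
tissue: five nonendogenous heptadecanoyl (N-17:0) NAPEs spiked into ~100 mg
aliquots at nine concentration levels from 10 to 2300 pmol/g, processed in
triplicate, with a constant 50 pmol spike of the PE 18:1/18:1-N-19:0
internal standard; accuracy QCs at 50/400/1400 pmol/g; precision from
separately processed replicates.  Relative instrument sensitivities span
the 0.5-1.1 range (relative to the internal standard) that per-analyte
calibration slopes typically show.
"""

from __future__ import annotations

from .lipid_model import FattyAcyl, NapeSpecies, parse_name
from .retention import RetentionModel, fit_retention
from .simulate import DEFAULT_IS_NAME, DEFAULT_RESPONSE_FACTOR, SamplePlan
from .transitions import MethodTable, build_method, enumerate_species

__all__ = [
    "HEPTADECANOYL_ANALYTES",
    "RELATIVE_RESPONSE",
    "CALIBRATION_LEVELS",
    "QC_LEVELS",
    "reference_retention_model",
    "validation_species",
    "validation_method",
    "validation_template",
    "brain_candidate_species",
]

#: The five nonendogenous N-17:0 spike analytes used for validation.
HEPTADECANOYL_ANALYTES = [
    "PE 34:1-N-17:0",
    "PE 34:2-N-17:0",
    "PE 36:1-N-17:0",
    "PE 36:2-N-17:0",
    "PE 38:4-N-17:0",
]

#: Instrument response relative to the internal standard.
RELATIVE_RESPONSE = {
    "PE 34:1-N-17:0": 0.74,
    "PE 34:2-N-17:0": 0.52,
    "PE 36:1-N-17:0": 0.66,
    "PE 36:2-N-17:0": 0.85,
    "PE 38:4-N-17:0": 1.13,
}

#: Nine calibration levels, pmol per g tissue.
CALIBRATION_LEVELS = [10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 1600.0, 2300.0]

#: Accuracy QC levels (low / medium / high), pmol per g tissue.
QC_LEVELS = [50.0, 400.0, 1400.0]


def reference_retention_model(run_length_min: float = 18.0) -> RetentionModel:
    """Retention model fitted to noiseless homologous-series observations.

    The synthetic observations follow rt = 2.0 + 0.30*(C+n) - 0.55*(D+dn)
    minutes, a carbon/double-bond trade-off that places the C50-C60 NAPE
    range in the back half of an 18-min reversed-phase run.
    """
    obs = []
    for c, d in [(50, 1), (52, 2), (54, 2), (54, 4), (56, 3), (58, 6)]:
        sp = NapeSpecies.species(c - 16, d, FattyAcyl(16, 0))
        obs.append((sp, 2.0 + 0.30 * c - 0.55 * d))
    return fit_retention(obs, run_length_min=run_length_min)


def validation_species() -> list[NapeSpecies]:
    return [parse_name(s) for s in HEPTADECANOYL_ANALYTES + [DEFAULT_IS_NAME]]


def validation_method(rt_model: RetentionModel | None = None, **kwargs) -> MethodTable:
    if rt_model is None:
        rt_model = reference_retention_model()
    return build_method(validation_species(), rt_model, **kwargs)


def response_factors() -> dict[str, float]:
    rfs = {k: v * DEFAULT_RESPONSE_FACTOR for k, v in RELATIVE_RESPONSE.items()}
    rfs[DEFAULT_IS_NAME] = DEFAULT_RESPONSE_FACTOR
    return rfs


def validation_template(seed: int, prep_cv: float = 0.05) -> SamplePlan:
    """Template plan for the calibration twin (amounts filled per level)."""
    return SamplePlan(
        species_amounts={a: 0.0 for a in HEPTADECANOYL_ANALYTES},
        response_factors=response_factors(),
        prep_cv=prep_cv,
        seed=seed,
    )


#: PE bodies commonly reported for rat brain glycerophosphoethanolamine.
BRAIN_PE_BODIES = [
    (32, 0),
    (34, 0),
    (34, 1),
    (34, 2),
    (36, 1),
    (36, 2),
    (36, 4),
    (38, 4),
    (38, 5),
    (38, 6),
    (40, 4),
    (40, 6),
]

#: Six N-acyl chains covering the saturated/monounsaturated/polyunsaturated
#: amide-linked fatty acids reported in brain NAPE pools.
BRAIN_N_ACYLS = [
    FattyAcyl(16, 0),
    FattyAcyl(18, 0),
    FattyAcyl(18, 1),
    FattyAcyl(18, 2),
    FattyAcyl(20, 4),
    FattyAcyl(22, 6),
]


def brain_candidate_species() -> list[NapeSpecies]:
    """Endogenous candidate list: brain PE bodies x six N-acyl chains."""
    return enumerate_species(BRAIN_PE_BODIES, BRAIN_N_ACYLS)
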