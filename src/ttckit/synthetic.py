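"""Seeded synthetic datasets with the statistical structure of a curated
industrial-chemicals TTC dataset.

The generator emulates the published dataset profile: ~656 retained
substances in a structural-class mixture of roughly 29% / 3% / 68%
(Classes I/II/III), class-conditional lognormal adjusted-POD
distributions with geometric means 12.5 / 2.6 / 4.7 mg/kg bw/day, a
74%/26% subacute/subchronic duration split, a minority of LOAEL-only
studies, and ~10.5% excluded-group structures (77 of 733).  Structures
are drawn from a hand-curated exemplar library whose expected classes
are regression-tested against the classifier.

Latent values are generated *backwards*: the target adjusted POD is
sampled first, then multiplied by the LOAEL and duration factors the
study is assigned, so the analysis pipeline must invert those factors
exactly to recover it.  All latents are recorded for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .records import (
    CramerClass,
    DoseUnit,
    EffectLevelType,
    ExclusionCategory,
    Route,
    StudyRecord,
    StudySource,
    SubstanceRecord,
)

# ---------------------------------------------------------------------------
# Exemplar structure library.  Each entry is (name, smiles, expected class).
# Classes are properties of the packaged decision tree and are verified by
# the test suite, so the generator's labels and the classifier never drift
# apart.

CLASS_I_EXEMPLARS: list[tuple[str, str]] = [
    ("ethanol", "CCO"),
    ("1-propanol", "CCCO"),
    ("1-butanol", "CCCCO"),
    ("1-pentanol", "CCCCCO"),
    ("1-hexanol", "CCCCCCO"),
    ("ethyl acetate", "CCOC(C)=O"),
    ("propyl acetate", "CCCOC(C)=O"),
    ("butyl acetate", "CCCCOC(C)=O"),
    ("pentyl acetate", "CCCCCOC(C)=O"),
    ("hexyl acetate", "CCCCCCOC(C)=O"),
    ("isoamyl acetate", "CC(C)CCOC(C)=O"),
    ("acetone", "CC(C)=O"),
    ("2-butanone", "CCC(C)=O"),
    ("acetic acid", "CC(=O)O"),
    ("propionic acid", "CCC(=O)O"),
    ("butyric acid", "CCCC(=O)O"),
    ("glycerol", "OCC(O)CO"),
    ("propylene glycol", "CC(O)CO"),
    ("diethyl ether", "CCOCC"),
    ("2-ethyl-1-hexanol", "CCCCC(CC)CO"),
    ("1-octene", "C=CCCCCCC"),
    ("toluene", "Cc1ccccc1"),
    ("p-xylene", "Cc1ccc(C)cc1"),
    ("p-cresol", "Cc1ccc(O)cc1"),
    ("4-tert-butylphenol", "CC(C)(C)c1ccc(O)cc1"),
    ("vanillin", "COc1cc(C=O)ccc1O"),
    ("benzyl acetate", "CC(=O)OCc1ccccc1"),
    ("cyclohexanol", "OC1CCCCC1"),
    ("cyclohexanone", "O=C1CCCCC1"),
]

CLASS_II_EXEMPLARS: list[tuple[str, str]] = [
    ("2-methylpyrazine", "Cc1cnccn1"),
    ("2,3-dimethylpyrazine", "Cc1nccnc1C"),
    ("2,3,5-trimethylpyrazine", "Cc1cnc(C)c(C)n1"),
    ("2-ethylpyrazine", "CCc1cnccn1"),
    ("furfural", "O=Cc1ccco1"),
    ("furfuryl alcohol", "OCc1ccco1"),
    ("2-acetylfuran", "CC(=O)c1ccco1"),
    ("maltol", "CC1=C(O)C(=O)C=CO1"),
    ("2-acetylpyrrole", "CC(=O)c1ccc[nH]1"),
]

CLASS_III_EXEMPLARS: list[tuple[str, str]] = [
    ("aniline", "Nc1ccccc1"),
    ("2,4-dimethylaniline", "Cc1ccc(N)c(C)c1"),
    ("3-methoxyaniline", "COc1cccc(N)c1"),
    ("N-ethylaniline", "CCNc1ccccc1"),
    ("N,N-dimethylaniline", "CN(C)c1ccccc1"),
    ("4-chloroaniline", "Nc1ccc(Cl)cc1"),
    ("4,4'-methylenedianiline", "Nc1ccc(Cc2ccc(N)cc2)cc1"),
    ("3,3',4,4'-tetrachloroazobenzene", "Clc1ccc(N=Nc2ccc(Cl)c(Cl)c2)cc1Cl"),
    ("azobenzene", "c1ccc(N=Nc2ccccc2)cc1"),
    ("6-n-propyl-2-thiouracil", "CCCC1=CC(=O)NC(=S)N1"),
    ("2-mercaptobenzimidazole", "S=C1Nc2ccccc2N1"),
    ("2-imidazolidinethione", "S=C1NCCN1"),
    ("thiourea", "NC(N)=S"),
    ("phenobarbital", "CCC1(c2ccccc2)C(=O)NC(=O)NC1=O"),
    ("WY-14,643", "Cc1cccc(Nc2cc(Cl)nc(SCC(=O)O)n2)c1C"),
    ("perfluoroundecanoic acid",
     "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"),
    ("2-(2'-hydroxy-3',5'-di-tert-butylphenyl)benzotriazole",
     "Oc1c(cc(cc1C(C)(C)C)C(C)(C)C)-n1nc2ccccc2n1"),
    ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
    ("benzonitrile", "N#Cc1ccccc1"),
    ("acrylonitrile", "C=CC#N"),
    ("acrolein", "C=CC=O"),
    ("pyridine", "c1ccncc1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("morpholine", "C1COCCN1"),
    ("cyclohexylamine", "NC1CCCCC1"),
    ("n-butylamine", "CCCCN"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("1,2-dichloroethane", "ClCCCl"),
]

CLASS_EXEMPLARS: dict[CramerClass, list[tuple[str, str]]] = {
    CramerClass.I: CLASS_I_EXEMPLARS,
    CramerClass.II: CLASS_II_EXEMPLARS,
    CramerClass.III: CLASS_III_EXEMPLARS,
}

#: Exemplars of the excluded substance groups; the natural-toxin entries
#: are list-based (input flag), not structural.
EXCLUDED_EXEMPLARS: dict[ExclusionCategory, list[tuple[str, str]]] = {
    ExclusionCategory.inorganic: [
        ("sodium chloride", "[Na+].[Cl-]"),
        ("sulfuric acid", "OS(=O)(=O)O"),
        ("ammonia", "N"),
    ],
    ExclusionCategory.organometal: [
        ("tetraethyllead", "CC[Pb](CC)(CC)CC"),
        ("sodium benzoate", "[Na+].[O-]C(=O)c1ccccc1"),
        ("zinc diacetate", "CC(=O)[O-].CC(=O)[O-].[Zn+2]"),
    ],
    ExclusionCategory.organophosphorus: [
        ("trimethyl phosphate", "COP(=O)(OC)OC"),
        ("tributyl phosphate", "CCCCOP(=O)(OCCCC)OCCCC"),
        ("triphenyl phosphate", "O=P(Oc1ccccc1)(Oc1ccccc1)Oc1ccccc1"),
    ],
    ExclusionCategory.organosilicon: [
        ("hexamethyldisiloxane", "C[Si](C)(C)O[Si](C)(C)C"),
        ("tetraethoxysilane", "CCO[Si](OCC)(OCC)OCC"),
        ("trimethylsilanol", "C[Si](C)(C)O"),
    ],
    ExclusionCategory.steroid: [
        ("testosterone", "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O"),
        ("estradiol", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O"),
        ("progesterone", "CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C"),
    ],
    ExclusionCategory.azoxy: [
        ("azoxybenzene", "[O-][N+](=Nc1ccccc1)c1ccccc1"),
        ("azoxymethane", "C/N=[N+](\\[O-])C"),
    ],
    ExclusionCategory.natural_toxin: [
        ("nicotine", "CN1CCCC1c1cccnc1"),
        ("coniine", "CCCC1CCCNC1"),
    ],
}


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic dataset generator.

    Defaults reproduce the published dataset profile; the Class II
    log-sigma is a placeholder (the real Class II is too small to
    constrain a spread parameter).
    """

    n_substances: int = Field(default=656, ge=1)
    class_mix: dict[CramerClass, float] = {
        CramerClass.I: 0.29,
        CramerClass.II: 0.03,
        CramerClass.III: 0.68,
    }
    class_gm: dict[CramerClass, float] = {
        CramerClass.I: 12.5,
        CramerClass.II: 2.6,
        CramerClass.III: 4.7,
    }
    class_log_sigma: dict[CramerClass, float] = {
        CramerClass.I: 1.606,
        CramerClass.II: 1.0,
        CramerClass.III: 1.951,
    }
    subacute_fraction: float = Field(default=0.74, ge=0, le=1)
    loael_only_fraction: float = Field(default=0.10, ge=0, le=1)
    excluded_fraction: float = Field(default=77 / 733, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "GeneratorConfig":
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        if any(v <= 0 for v in self.class_gm.values()):
            raise ValueError("class geometric means must be positive")
        if any(v < 0 for v in self.class_log_sigma.values()):
            raise ValueError("class log-sigmas must be nonnegative")
        return self


@dataclass
class GeneratorTruth:
    """Latent values behind a generated dataset, for recovery tests."""

    classes: dict[str, CramerClass] = field(default_factory=dict)
    excluded: dict[str, ExclusionCategory] = field(default_factory=dict)
    critical_adjusted_pod: dict[str, float] = field(default_factory=dict)
    study_adjusted_pod: dict[tuple[str, int], float] = field(default_factory=dict)
    config: Optional[GeneratorConfig] = None


# Source mixtures conditional on duration category, mirroring the
# published per-source study counts (subacute studies come almost
# entirely from the national existing-chemicals program; subchronic
# studies mostly from range-finding studies).
_SUBACUTE_SOURCES = (
    (StudySource.CSCL, 431 / 488),
    (StudySource.OECD_SIDS, 43 / 488),
    (StudySource.journal, 10 / 488),
    (StudySource.NTP, 4 / 488),
)
_SUBCHRONIC_SOURCES = (
    (StudySource.NTP, 121 / 168),
    (StudySource.OECD_SIDS, 32 / 168),
    (StudySource.ISHA, 11 / 168),
    (StudySource.journal, 4 / 168),
)

_ROUTES = (
    (Route.gavage, 0.6),
    (Route.dietary, 0.3),
    (Route.drinking_water, 0.1),
)


def _choice(rng: np.random.Generator, weighted):
    items = [w[0] for w in weighted]
    probs = np.array([w[1] for w in weighted], dtype=float)
    return items[rng.choice(len(items), p=probs / probs.sum())]


def _make_studies(
    rng: np.random.Generator,
    sid: str,
    config: GeneratorConfig,
    critical_adjusted: float,
    truth: GeneratorTruth,
) -> list[StudyRecord]:
    n_studies = int(rng.integers(1, 4))
    studies = []
    for j in range(n_studies):
        if j == 0:
            adjusted = critical_adjusted
            reliability = 1
        else:
            # Companion studies: correlated but less reliable, so the
            # critical study always wins selection on reliability.
            adjusted = critical_adjusted * float(
                np.exp(rng.normal(0.0, 0.5))
            )
            reliability = int(rng.integers(2, 4))
        subacute = rng.random() < config.subacute_fraction
        duration = int(rng.integers(28, 84) if subacute else rng.integers(84, 180))
        dur_factor = 6 if subacute else 3
        loael = rng.random() < config.loael_only_fraction
        loael_factor = 3 if loael else 1
        studies.append(
            StudyRecord(
                substance_id=sid,
                source=_choice(rng, _SUBACUTE_SOURCES if subacute else _SUBCHRONIC_SOURCES),
                route=_choice(rng, _ROUTES),
                duration_days=duration,
                effect_level_type=(
                    EffectLevelType.LOAEL if loael else EffectLevelType.NOAEL
                ),
                effect_level=adjusted * dur_factor * loael_factor,
                dose_unit=DoseUnit.mg_kg_bw_day,
                reliability_rank=reliability,
            )
        )
        truth.study_adjusted_pod[(sid, j)] = adjusted
    return studies


def _make_substance(
    rng: np.random.Generator,
    index: int,
    label: CramerClass | ExclusionCategory,
    config: GeneratorConfig,
    truth: GeneratorTruth,
) -> tuple[SubstanceRecord, list[StudyRecord]]:
    sid = f"SYN{index:05d}"
    if isinstance(label, CramerClass):
        name, smiles = CLASS_EXEMPLARS[label][
            int(rng.integers(len(CLASS_EXEMPLARS[label])))
        ]
        gm = config.class_gm[label]
        sigma = config.class_log_sigma[label]
        truth.classes[sid] = label
        flag = False
    else:
        name, smiles = EXCLUDED_EXEMPLARS[label][
            int(rng.integers(len(EXCLUDED_EXEMPLARS[label])))
        ]
        # Excluded substances never reach the fit; give them the broad
        # Class III dose distribution.
        gm = config.class_gm[CramerClass.III]
        sigma = config.class_log_sigma[CramerClass.III]
        truth.excluded[sid] = label
        flag = label is ExclusionCategory.natural_toxin
    critical_adjusted = float(np.exp(rng.normal(math.log(gm), sigma)))
    truth.critical_adjusted_pod[sid] = critical_adjusted
    substance = SubstanceRecord(
        substance_id=sid,
        name=name,
        smiles=smiles,
        natural_toxin_flag=flag,
    )
    return substance, _make_studies(rng, sid, config, critical_adjusted, truth)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[SubstanceRecord], list[StudyRecord], GeneratorTruth]:
    """Generate a seeded synthetic dataset.

    Returns substances, studies (1-3 per substance, the critical one at
    reliability rank 1), and the latent truth for recovery tests.  Output
    is a pure function of the config, including the seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = GeneratorTruth(config=config)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    excluded_cats = list(EXCLUDED_EXEMPLARS)

    substances: list[SubstanceRecord] = []
    studies: list[StudyRecord] = []
    for i in range(config.n_substances):
        if rng.random() < config.excluded_fraction:
            label: CramerClass | ExclusionCategory = excluded_cats[
                int(rng.integers(len(excluded_cats)))
            ]
        else:
            label = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
        substance, sub_studies = _make_substance(rng, i, label, config, truth)
        substances.append(substance)
        studies.extend(sub_studies)
    return substances, studies, truth


#: Composition of the 733-substance curation fixture: 77 excluded-group
#: structures (18 organosilicon, matching the published count) and
#: 656 retained substances split 190 / 22 / 444 across Classes I/II/III.
FIXTURE_733_EXCLUDED = {
    ExclusionCategory.inorganic: 10,
    ExclusionCategory.organometal: 15,
    ExclusionCategory.organophosphorus: 16,
    ExclusionCategory.organosilicon: 18,
    ExclusionCategory.steroid: 6,
    ExclusionCategory.azoxy: 5,
    ExclusionCategory.natural_toxin: 7,
}
FIXTURE_733_CLASSES = {
    CramerClass.I: 190,
    CramerClass.II: 22,
    CramerClass.III: 444,
}


def fixture_733(
    seed: int = 0,
) -> tuple[list[SubstanceRecord], list[StudyRecord], GeneratorTruth]:
    """Deterministic 733-substance dataset: exactly 77 excluded-group
    structures; curation retains exactly 656 substances."""
    config = GeneratorConfig(n_substances=733, seed=seed)
    rng = np.random.default_rng(config.seed)
    truth = GeneratorTruth(config=config)

    labels: list[CramerClass | ExclusionCategory] = []
    for category, count in FIXTURE_733_EXCLUDED.items():
        labels.extend([category] * count)
    for cls, count in FIXTURE_733_CLASSES.items():
        labels.extend([cls] * count)
    assert len(labels) == 733
    rng.shuffle(labels)  # type: ignore[arg-type]

    substances: list[SubstanceRecord] = []
    studies: list[StudyRecord] = []
    for i, label in enumerate(labels):
        substance, sub_studies = _make_substance(rng, i, label, config, truth)
        substances.append(substance)
        studies.extend(sub_studies)
    return substances, studies, truth
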