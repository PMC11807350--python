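"""Shared template bank: type-characteristic cue phrases and sentence
skeletons used by the synthetic-corpus generator and the bundled
template stand-in for the prompt-based sentence generator.

Cue phrases are unique to their top-level type, which guarantees that a
bag-of-words model can separate the classes on generated fixtures — the
property that makes desk-scale pipeline smoke tests meaningful.  Each
type also maps to one designated fine-grained sub-category (where one
exists) so fixtures can exercise fine granularity.
"""

from __future__ import annotations

__all__ = ["CUE_PHRASES", "FINE_FOR_TOP", "SAL_SKELETONS", "FILLER_SENTENCES"]

#: Per top-level type: cue phrases that occur in no other type's templates.
CUE_PHRASES: dict[str, list[str]] = {
    "StudyDesign": ["crossover design", "cluster allocation", "factorial scheme"],
    "Population": ["highly selected participants", "restrictive inclusion criteria", "narrow patient spectrum"],
    "Setting": ["single center", "one recruiting site", "unicentric setting"],
    "Intervention": ["multimodal treatment components", "nonstandardized dosage", "heterogeneous delivery of therapy"],
    "Control": ["no placebo arm", "active comparator only", "usual care comparison"],
    "OutcomeMeasures": ["unvalidated instrument", "insensitive outcome scale", "surrogate endpoint reliance"],
    "MissingData": ["incomplete follow-up data", "unrecorded covariates", "attrition of records"],
    "UnderpoweredStudy": ["small sample size", "insufficient statistical power", "few outcome events"],
    "Randomization": ["imbalanced baseline groups", "predictable allocation sequence", "inadequate concealment"],
    "Blinding": ["unblinded assessors", "participants aware of assignment", "open label administration"],
    "StudyDuration": ["short follow-up period", "brief intervention phase", "limited observation window"],
    "StatisticalAnalysis": ["multiple comparisons", "unadjusted confounders", "exploratory subgroup testing"],
    "Funding": ["lack of funding", "limited financial support", "budget constraints on the trial"],
    "Generalization": ["limited external validity", "findings may not transfer", "context specific results"],
    "Other": ["miscellaneous methodological issue", "unclassified weakness", "idiosyncratic constraint"],
}

#: One designated sub-category per top-level type (empty when none exists).
FINE_FOR_TOP: dict[str, str] = {
    "Population": "VerySpecificPopulation",
    "Setting": "Unicentric",
    "Intervention": "CompositeIntervention",
    "Control": "NoPlaceboGroup",
    "OutcomeMeasures": "ValidityOfMeasurement",
    "MissingData": "HighLossToFollowUp",
    "UnderpoweredStudy": "SampleSize",
    "Randomization": "UnbalancedGroups",
    "Blinding": "Patient",
    "StudyDuration": "FollowUpDuration",
    "StatisticalAnalysis": "MultipleTesting",
    "StudyDesign": "",
    "Funding": "",
    "Generalization": "",
    "Other": "",
}

#: Skeletons into which a cue phrase is substituted to build a SAL sentence.
SAL_SKELETONS: list[str] = [
    "A limitation of this trial is the {cue}.",
    "Our findings should be interpreted with caution because of the {cue}.",
    "The {cue} may have biased the observed effect.",
    "We acknowledge that the {cue} restricts the conclusions.",
    "Results could be affected by the {cue} in this study.",
    "Another weakness concerns the {cue} noted during the trial.",
]

#: Neutral filler sentences for non-SAL positions.
FILLER_SENTENCES: list[str] = [
    "Participants were recruited between 2015 and 2018.",
    "The primary endpoint was assessed at twelve weeks.",
    "Baseline characteristics were similar across arms.",
    "Adverse events were recorded throughout the trial.",
    "The protocol was approved by the ethics committee.",
    "Analyses followed the intention to treat principle.",
    "Mean age of the cohort was fifty four years.",
    "Treatment adherence exceeded ninety percent overall.",
    "Secondary endpoints included quality of life scores.",
    "Data were collected using electronic case report forms.",
]
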