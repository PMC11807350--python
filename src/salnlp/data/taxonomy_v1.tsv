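# salnlp taxonomy	version=1.0
# columns: name, level (top|fine), parent (empty for top), description
name	level	parent	description
StudyDesign	top		Limitations that have to do with the specific trial design used (e.g., crossover, factorial, cluster).
Population	top		Limitations that have to do with the selection of subjects who participated in the trial.
DiagnosticCriteria	fine	Population	Lack of standardized diagnostic criteria for including participants.
VerySpecificPopulation	fine	Population	Inclusion criteria considered too restricted (e.g., single gender, athletes only, education level, or race).
ConvenienceSampling	fine	Population	Subjects were selected because they were convenient sources of data for the study.
Setting	top		Limitations related to where the study takes place.
Unicentric	fine	Setting	Study was conducted recruiting participants from a single center.
Intervention	top		Limitations that have to do with the active intervention treatment used.
CompositeIntervention	fine	Intervention	It was not possible to know the net effect of every component in multimodal treatments.
NonStandardTreatmentCharacteristics	fine	Intervention	The specific parameters for the intervention were not standardized (e.g., dosage, mode of administration).
Control	top		Limitations that have to do with the control intervention or placebo.
NoPlaceboGroup	fine	Control	No control intervention is included.
ActivePlacebo	fine	Control	An active intervention (non-inert) was selected as control.
CareAsUsualControlGroup	fine	Control	Non-standardized care-as-usual control; it is uncertain what the experimental group is being compared to.
OutcomeMeasures	top		Limitations related to the outcomes used and how they are measured.
RelevantOutcomeExcluded	fine	OutcomeMeasures	Some relevant data that would potentially provide interesting findings were not collected during the study.
PrecisionOfMeasurement	fine	OutcomeMeasures	Lack of or low precision of outcome measures (random measurement error).
ValidityOfMeasurement	fine	OutcomeMeasures	The selected assessment instrument was not originally validated for the specific population or problem studied.
ResponsivenessOfMeasurement	fine	OutcomeMeasures	Outcome measures were not sensitive enough to detect subtle changes.
MissingData	top		Some planned follow-up measurements, whether outcomes or co-variables, were not collected for some participants.
HighLossToFollowUp	fine	MissingData	Many participants stopped participating before the planned duration of follow-up.
UnbalancedDropout	fine	MissingData	Characteristics of dropped-out patients differed between groups (informative drop-out).
UnderpoweredStudy	top		Inability to detect differences between groups due to sample size or insufficient number of outcome events.
SampleSize	fine	UnderpoweredStudy	Insufficient number of patients participating in the trial, possibly due to recruitment difficulties.
Randomization	top		Limitations that have to do with the randomization of patients into different trial arms.
UnbalancedGroups	fine	Randomization	After randomization, large differences between groups with respect to prognostically important factors.
PoorRandomizationMethods	fine	Randomization	Randomization methods (sequence generation, stratification, concealment) were not optimal or absent.
Blinding	top		Limitations related to how the study participants and personnel were blinded to the study groups.
Patient	fine	Blinding	Patients were not blinded with respect to the study groups.
StudyTeam	fine	Blinding	Some people in the study team (investigators, care providers, assessors, statisticians) are not blinded.
StudyDuration	top		Limitations that have to do with the length of the study, experimental phase or follow-up.
ExperimentPhaseDuration	fine	StudyDuration	The intervention phase is too short, possibly due to early stopping.
FollowUpDuration	fine	StudyDuration	Only short-term effects were evaluated; long-term effects were not considered.
StatisticalAnalysis	top		Limitations regarding the statistical analysis methods, which may not have been appropriate or were suboptimal.
MultipleTesting	fine	StatisticalAnalysis	Simultaneous testing of more than one hypothesis.
ConfoundingFactors	fine	StatisticalAnalysis	Findings were not adjusted for covariates.
Funding	top		The limited or lack of funding affected the study progress or completion.
Generalization	top		Results may not generalize due to type of setting, specific population, intervention, or measurement instruments.
Other	top		Catch-all category for limitation types that do not neatly fit in any other category.
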