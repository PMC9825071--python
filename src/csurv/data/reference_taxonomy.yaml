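# Full 18-theme reference taxonomy.
# The ten themes of the harmonised reference subset are fully specified
# (see table1_taxonomy.yaml); the Administrative data theme is attested by
# name but its number and content are not settled, and the remaining seven
# slots are placeholders.  All such stubs carry `provisional: true` and may
# be relabelled/populated as the model is extended; the theme count (18) is
# stable.  Beyond the 32-object harmonised subset, the Structural family
# additionally carries the Height and Weight objects (the anthropometry the
# metric-conversion conventions are defined for); the 32-object subset
# itself lives unchanged in table1_taxonomy.yaml.
version: '1.0'
themes:
- index: 1
  label: Administrative data
  provisional: true
- index: 2
  label: Sociodemographic
  children:
  - label: Demographic indicators
    children:
    - label: Age
      children:
      - label: Year of birth
      - label: Age
    - label: Gender
      children:
      - label: Sex
  - label: Education
    children:
    - label: Educational experience
      children:
      - label: Years education
- index: 3
  label: Theme 3 (provisional)
  provisional: true
- index: 4
  label: Medical history
  children:
  - label: Nervous system
    children:
    - label: Chronic neurological disorders
      children:
      - label: Dementia Diagnosis
      - label: PD Diagnosis
    - label: Episodic disorders
      children:
      - label: Episodic disorders
    - label: Other neurological disorders
      children:
      - label: Other neurological disorders
  - label: Circulatory
    children:
    - label: Cardiovascular disorders
      children:
      - label: CVD
      - label: Stroke
  - label: Self-report medical history
    children:
    - label: General health
      children:
      - label: MCI
    - label: Medications self-report
      children:
      - label: Prescription medications
- index: 5
  label: Family disease history
  children:
  - label: Nervous system
    children:
    - label: Chronic neurological disorder
      children:
      - label: Family history dementia
      - label: Family history PD
  - label: Circulatory
    children:
    - label: Cardiovascular
      children:
      - label: Family history stroke
- index: 6
  label: Psychological status
  children:
  - label: Self-report mental health
    children:
    - label: Depression
      children:
      - label: Depression scale
    - label: Trauma
      children:
      - label: PTSD
- index: 7
  label: Cognitive status
  children:
  - label: Memory
    children:
    - label: Short term/working memory
      children:
      - label: Immediate recall
    - label: Long term
      children:
      - label: Delayed recall
  - label: Problem solving
    children:
    - label: Planning
      children:
      - label: Executive function task
  - label: Processing speed
    children:
    - label: Task response time
      children:
      - label: Reaction time task
  - label: Self-report
    children:
    - label: Memory
      children:
      - label: Subjective memory complaint
    - label: Cognition
      children:
      - label: Cognitive impairment
- index: 8
  label: Lifestyle behaviour
  children:
  - label: Substance use
    children:
    - label: Alcohol
      children:
      - label: Alcohol units/wk
    - label: Tobacco
      children:
      - label: Smoking status
- index: 9
  label: Theme 9 (provisional)
  provisional: true
- index: 10
  label: Theme 10 (provisional)
  provisional: true
- index: 11
  label: Theme 11 (provisional)
  provisional: true
- index: 12
  label: Physical examination
  children:
  - label: Musculo-skeletal
    children:
    - label: Structural
      children:
      - label: BMI
      - label: Height
      - label: Weight
  - label: Circulatory
    children:
    - label: Cardiovascular
      children:
      - label: BP systolic
      - label: BP Diastolic
- index: 13
  label: Imaging
  children:
  - label: Brain
    children:
    - label: MRI
      children:
      - label: MRI images
- index: 14
  label: Theme 14 (provisional)
  provisional: true
- index: 15
  label: Theme 15 (provisional)
  provisional: true
- index: 16
  label: Bio-sample assays
  children:
  - label: Blood
    children:
    - label: Haematology
      children:
      - label: CRP
  - label: CSF
    children:
    - label: Proteins
      children:
      - label: CSF Tau
- index: 17
  label: Molecular
  children:
  - label: Genomics
    children:
    - label: SNP
      children:
      - label: APOE
- index: 18
  label: Theme 18 (provisional)
  provisional: true
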