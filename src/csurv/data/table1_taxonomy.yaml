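# Harmonised-variable reference subset: 10 themes, 32 objects.
# Theme indices are the printed theme numbers (hence non-contiguous).
# Note: Psychological status is numbered 6 here; one prose passage of the
# source material calls it category 10 — the tabulated numbering is followed.
# "Episodic disorders" and "Other neurological disorders" are single-object
# families (the object is the disorder group itself); the family-history
# families record the family-member relation alongside the disorder class.
version: "1.0"
themes:
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
  - index: 12
    label: Physical examination
    children:
      - label: Musculo-skeletal
        children:
          - label: Structural
            children:
              - label: BMI
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
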