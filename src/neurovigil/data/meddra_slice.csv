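pt,hlgt,soc
Encephalitis,Central nervous system infections and inflammations,Nervous system disorders
Immune-mediated encephalitis,Central nervous system infections and inflammations,Nervous system disorders
Autoimmune encephalitis,Central nervous system infections and inflammations,Nervous system disorders
Noninfective encephalitis,Central nervous system infections and inflammations,Nervous system disorders
Meningitis aseptic,Central nervous system infections and inflammations,Nervous system disorders
Myelitis,Central nervous system infections and inflammations,Nervous system disorders
Meningoradiculitis,Central nervous system infections and inflammations,Nervous system disorders
Paraneoplastic encephalomyelitis,Central nervous system infections and inflammations,Nervous system disorders
Encephalopathy,Encephalopathies,Nervous system disorders
Immune-mediated encephalopathy,Encephalopathies,Nervous system disorders
Toxic encephalopathy,Encephalopathies,Nervous system disorders
Posterior reversible encephalopathy syndrome,Encephalopathies,Nervous system disorders
Immune-mediated neurological disorder,Neurological disorders NEC,Nervous system disorders
Paraneoplastic neurological syndrome,Neurological disorders NEC,Nervous system disorders
Neurotoxicity,Neurological disorders NEC,Nervous system disorders
Altered state of consciousness,Neurological disorders NEC,Nervous system disorders
Loss of consciousness,Neurological disorders NEC,Nervous system disorders
Syncope,Neurological disorders NEC,Nervous system disorders
Dizziness,Neurological disorders NEC,Nervous system disorders
Somnolence,Neurological disorders NEC,Nervous system disorders
Neuropathy peripheral,Peripheral nervous system disorders,Nervous system disorders
Peripheral sensory neuropathy,Peripheral nervous system disorders,Nervous system disorders
Peripheral motor neuropathy,Peripheral nervous system disorders,Nervous system disorders
Polyneuropathy,Peripheral nervous system disorders,Nervous system disorders
Guillain-Barre syndrome,Peripheral nervous system disorders,Nervous system disorders
Immune-mediated neuropathy,Peripheral nervous system disorders,Nervous system disorders
Neuritis,Peripheral nervous system disorders,Nervous system disorders
Neuropathy cranial,Peripheral nervous system disorders,Nervous system disorders
Demyelinating polyneuropathy,Peripheral nervous system disorders,Nervous system disorders
Chronic inflammatory demyelinating polyradiculoneuropathy,Peripheral nervous system disorders,Nervous system disorders
Axonal neuropathy,Peripheral nervous system disorders,Nervous system disorders
Mononeuropathy,Peripheral nervous system disorders,Nervous system disorders
Cerebral infarction,Central nervous system vascular disorders,Nervous system disorders
Cerebral haemorrhage,Central nervous system vascular disorders,Nervous system disorders
Ischaemic stroke,Central nervous system vascular disorders,Nervous system disorders
Transient ischaemic attack,Central nervous system vascular disorders,Nervous system disorders
Parkinsonism,Movement disorders (incl parkinsonism),Nervous system disorders
Tremor,Movement disorders (incl parkinsonism),Nervous system disorders
Myasthenia gravis,Neuromuscular disorders,Nervous system disorders
Immune-mediated myasthenia gravis,Neuromuscular disorders,Nervous system disorders
Lambert-Eaton myasthenic syndrome,Neuromuscular disorders,Nervous system disorders
Myasthenic syndrome,Neuromuscular disorders,Nervous system disorders
Seizure,Seizures (incl subtypes),Nervous system disorders
Status epilepticus,Seizures (incl subtypes),Nervous system disorders
Generalised tonic-clonic seizure,Seizures (incl subtypes),Nervous system disorders
Headache,Headaches,Nervous system disorders
Migraine,Headaches,Nervous system disorders
Cognitive disorder,Mental impairment disorders,Nervous system disorders
Memory impairment,Mental impairment disorders,Nervous system disorders
Disturbance in attention,Mental impairment disorders,Nervous system disorders
Aphasia,Mental impairment disorders,Nervous system disorders
Hypoaesthesia,Sensory abnormalities NEC,Nervous system disorders
Paraesthesia,Sensory abnormalities NEC,Nervous system disorders
Dysgeusia,Sensory abnormalities NEC,Nervous system disorders
Taste disorder,Sensory abnormalities NEC,Nervous system disorders
Ageusia,Sensory abnormalities NEC,Nervous system disorders
Multiple sclerosis,Demyelinating disorders,Nervous system disorders
Demyelination,Demyelinating disorders,Nervous system disorders
Optic neuritis,Demyelinating disorders,Nervous system disorders
Immune-mediated optic neuritis,Demyelinating disorders,Nervous system disorders
Nausea,Gastrointestinal signs and symptoms,Gastrointestinal disorders
Vomiting,Gastrointestinal signs and symptoms,Gastrointestinal disorders
Diarrhoea,Gastrointestinal signs and symptoms,Gastrointestinal disorders
Constipation,Gastrointestinal signs and symptoms,Gastrointestinal disorders
Abdominal pain,Gastrointestinal signs and symptoms,Gastrointestinal disorders
Colitis,Gastrointestinal inflammatory conditions,Gastrointestinal disorders
Immune-mediated enterocolitis,Gastrointestinal inflammatory conditions,Gastrointestinal disorders
Fatigue,General system disorders NEC,General disorders and administration site conditions
Pyrexia,General system disorders NEC,General disorders and administration site conditions
Asthenia,General system disorders NEC,General disorders and administration site conditions
Oedema peripheral,General system disorders NEC,General disorders and administration site conditions
Rash,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
Pruritus,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
Dry skin,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
Vitiligo,Pigmentation disorders,Skin and subcutaneous tissue disorders
Hypothyroidism,Thyroid gland disorders,Endocrine disorders
Hyperthyroidism,Thyroid gland disorders,Endocrine disorders
Thyroiditis,Thyroid gland disorders,Endocrine disorders
Hypophysitis,Pituitary gland disorders,Endocrine disorders
Adrenal insufficiency,Adrenal gland disorders,Endocrine disorders
Pneumonitis,Lower respiratory tract disorders,"Respiratory, thoracic and mediastinal disorders"
Dyspnoea,Lower respiratory tract disorders,"Respiratory, thoracic and mediastinal disorders"
Cough,Lower respiratory tract disorders,"Respiratory, thoracic and mediastinal disorders"
Anaemia,Anaemias nonhaemolytic and marrow depression,Blood and lymphatic system disorders
Thrombocytopenia,Anaemias nonhaemolytic and marrow depression,Blood and lymphatic system disorders
Neutropenia,Anaemias nonhaemolytic and marrow depression,Blood and lymphatic system disorders
Arthralgia,Joint disorders,Musculoskeletal and connective tissue disorders
Myalgia,Muscle disorders,Musculoskeletal and connective tissue disorders
Immune-mediated myositis,Muscle disorders,Musculoskeletal and connective tissue disorders
Hepatitis,Hepatic and hepatobiliary disorders,Hepatobiliary disorders
Immune-mediated hepatitis,Hepatic and hepatobiliary disorders,Hepatobiliary disorders
Acute kidney injury,Renal disorders (excl nephropathies),Renal and urinary disorders
Decreased appetite,Appetite and general nutritional disorders,Metabolism and nutrition disorders
Hyperglycaemia,Glucose metabolism disorders (incl diabetes mellitus),Metabolism and nutrition disorders
Weight decreased,Physical examination and organ system status topics,Investigations
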