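fine_type	group
Activity	Activities & Behaviors
Behavior	Activities & Behaviors
Daily or Recreational Activity	Activities & Behaviors
Event	Activities & Behaviors
Governmental or Regulatory Activity	Activities & Behaviors
Individual Behavior	Activities & Behaviors
Machine Activity	Activities & Behaviors
Occupational Activity	Activities & Behaviors
Social Behavior	Activities & Behaviors
Anatomical Structure	Anatomy
Body Location or Region	Anatomy
Body Part, Organ, or Organ Component	Anatomy
Body Space or Junction	Anatomy
Body Substance	Anatomy
Body System	Anatomy
Cell	Anatomy
Cell Component	Anatomy
Embryonic Structure	Anatomy
Fully Formed Anatomical Structure	Anatomy
Tissue	Anatomy
Amino Acid, Peptide, or Protein	Chemicals & Drugs
Antibiotic	Chemicals & Drugs
Biologically Active Substance	Chemicals & Drugs
Biomedical or Dental Material	Chemicals & Drugs
Chemical	Chemicals & Drugs
Chemical Viewed Functionally	Chemicals & Drugs
Chemical Viewed Structurally	Chemicals & Drugs
Element, Ion, or Isotope	Chemicals & Drugs
Enzyme	Chemicals & Drugs
Hazardous or Poisonous Substance	Chemicals & Drugs
Hormone	Chemicals & Drugs
Immunologic Factor	Chemicals & Drugs
Indicator, Reagent, or Diagnostic Aid	Chemicals & Drugs
Inorganic Chemical	Chemicals & Drugs
Nucleic Acid, Nucleoside, or Nucleotide	Chemicals & Drugs
Receptor	Chemicals & Drugs
Vitamin	Chemicals & Drugs
Classification	Concepts & Ideas
Conceptual Entity	Concepts & Ideas
Group Attribute	Concepts & Ideas
Idea or Concept	Concepts & Ideas
Intellectual Product	Concepts & Ideas
Language	Concepts & Ideas
Quantitative Concept	Concepts & Ideas
Regulation or Law	Concepts & Ideas
Spatial Concept	Concepts & Ideas
Temporal Concept	Concepts & Ideas
Drug Delivery Device	Devices
Medical Device	Devices
Research Device	Devices
Disease or Syndrome	Disease or Syndrome
Acquired Abnormality	Disorders
Anatomical Abnormality	Disorders
Cell or Molecular Dysfunction	Disorders
Congenital Abnormality	Disorders
Experimental Model of Disease	Disorders
Injury or Poisoning	Disorders
Finding	Finding
Functional Concept	Functional Concept
Amino Acid Sequence	Genes & Molecular Sequences
Carbohydrate Sequence	Genes & Molecular Sequences
Gene or Genome	Genes & Molecular Sequences
Molecular Sequence	Genes & Molecular Sequences
Nucleotide Sequence	Genes & Molecular Sequences
Age Group	Living Beings
Amphibian	Living Beings
Animal	Living Beings
Archaeon	Living Beings
Bacterium	Living Beings
Bird	Living Beings
Eukaryote	Living Beings
Family Group	Living Beings
Fish	Living Beings
Fungus	Living Beings
Group	Living Beings
Human	Living Beings
Mammal	Living Beings
Organism	Living Beings
Patient or Disabled Group	Living Beings
Plant	Living Beings
Population Group	Living Beings
Professional or Occupational Group	Living Beings
Reptile	Living Beings
Vertebrate	Living Beings
Virus	Living Beings
Mental or Behavioral Dysfunction	Mental or Behavioral Dysfunction
Neoplastic Process	Neoplastic Process
Geographic Area	Objects
Entity	Objects
Food	Objects
Manufactured Object	Objects
Physical Object	Objects
Substance	Objects
Biomedical Occupation or Discipline	Occupations
Occupation or Discipline	Occupations
Organic Chemical	Organic Chemical
Health Care Related Organization	Organizations
Organization	Organizations
Professional Society	Organizations
Self-help or Relief Organization	Organizations
Pathologic Function	Pathologic Function
Clinical Drug	Pharmacologic Substance
Pharmacologic Substance	Pharmacologic Substance
Biologic Function	Phenomena
Environmental Effect of Humans	Phenomena
Human-caused Phenomenon or Process	Phenomena
Laboratory or Test Result	Phenomena
Natural Phenomenon or Process	Phenomena
Phenomenon or Process	Phenomena
Cell Function	Physiology
Clinical Attribute	Physiology
Genetic Function	Physiology
Mental Process	Physiology
Molecular Function	Physiology
Organ or Tissue Function	Physiology
Organism Attribute	Physiology
Organism Function	Physiology
Physiologic Function	Physiology
Diagnostic Procedure	Procedures
Educational Activity	Procedures
Health Care Activity	Procedures
Laboratory Procedure	Procedures
Molecular Biology Research Technique	Procedures
Research Activity	Procedures
Therapeutic or Preventive Procedure	Procedures
Qualitative Concept	Qualitative Concept
Sign or Symptom	Sign or Symptom
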