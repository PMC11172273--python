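# Default Medical-Dependent Feature (MDF) catalogue: 9 categories, 87 values.
# Format: categories -> {category name -> {canonical value -> [synonyms...]}}.
# Synonyms cover the common clinical abbreviations and spelling variants of
# the canonical value strings; matching is case-insensitive on token
# boundaries, so hyphenation differences ("X-Ray" / "x ray") need no entry
# while fused spellings ("xray") do.
categories:
  Radiology:
    Ultrasound Imaging: [ultrasound, sonography, ultrasonography]
    Magnetic Resonance Imaging: [MRI, MR imaging]
    Computerized Tomography: [CT, CT scan, computed tomography]
    X-Ray: [xray, radiograph]
    2D Radiography: []
    Angiography: [angiogram]
    PET: [positron emission tomography]
    Combined modalities in one image: []
    Coronarography: []
    Cystography: []
    Scintigraphy: []
    Mammography: [mammogram]
    Bone Densitometry: []
    Radiotherapy: []
    Urography: []
    Pelvic Ultrasound: []
    Myelography: []
    FibroScan: []
  Microscopy:
    Light Microscopy: []
    Electron Microscopy: []
    Transmission Microscopy: []
    Fluorescence Microscopy: []
    Biopsy: []
    Stool Microscopy: []
    Capillaroscopy: []
    Trophoblast Biopsy: []
    Cytology: []
  Visible light photography:
    Dermatology: []
    Skin: []
    Endoscopy: []
    Other organs: []
    Colposcopy: []
    Cystoscopy: []
    Hysteroscopy: []
  Printed signals and waves:
    Electroencephalography: [EEG]
    Electrocardiography: [ECG, EKG]
    Electromyography: [EMG]
    Holter: []
    Audiometry: []
    Urodynamic Assessment: []
  Generic Biomedical Illustrations:
    modality tables and forms: []
    program listing: []
    statistical figures: []
    graphs: []
    charts: []
    screen shots: [screenshots]
    flowcharts: []
    system overviews: []
    gene sequence: []
    chromatography: []
    gel: []
    chemical structure: []
    mathematics formula: []
    non-clinical photos: []
    hand-drawn sketches: []
  Dimensionality:
    macro: []
    micro: []
    small: []
    gross: []
    combined dimensionality: []
  V-Spec:
    brown: []
    black: []
    white: []
    red: []
    gray: [grey]
    green: []
    yellow: []
    blue: []
    colored: [coloured]
  T-spec:
    finding: []
    pathology: []
    differential diagnosis: []
    Amniocentesis: []
    Hemogram: []
    Non-Invasive Prenatal Screening: []
    Urinalysis: []
    Lumbar Puncture: []
    Seminogram: []
    Triple Test: []
  C-spec:
    Histology: []
    Fracture: []
    Cancer: []
    Benign: []
    Malignant: []
    Tumor: [tumour]
    Pregnancy: []
    Antibiogramme: []
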