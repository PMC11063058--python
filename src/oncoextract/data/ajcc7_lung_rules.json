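{
  "version": "ajcc7-lung/1.0",
  "description": "Declarative AJCC 7th-edition lung carcinoma staging rules: T size ladder, T descriptor minimums, N station levels, and the (T, N, M) stage grouping table. One citation string per rule for auditability.",
  "t_size_ladder": [
    {"max_cm": 2.0, "t": "T1a", "citation": "AJCC7 lung: tumor <=2 cm in greatest dimension -> T1a"},
    {"max_cm": 3.0, "t": "T1b", "citation": "AJCC7 lung: tumor >2 cm but <=3 cm -> T1b"},
    {"max_cm": 5.0, "t": "T2a", "citation": "AJCC7 lung: tumor >3 cm but <=5 cm -> T2a"},
    {"max_cm": 7.0, "t": "T2b", "citation": "AJCC7 lung: tumor >5 cm but <=7 cm -> T2b"},
    {"max_cm": null, "t": "T3", "citation": "AJCC7 lung: tumor >7 cm in greatest dimension -> T3"}
  ],
  "t_descriptor_rules": [
    {"flag": "visceral_pleura_surrounded_ok", "min_t": null, "citation": "AJCC7 lung: tumor surrounded by lung or visceral pleura without invasion is staged by size alone"},
    {"flag": "visceral_pleura_invaded", "min_t": "T2a", "citation": "AJCC7 lung: invasion of visceral pleura -> at least T2"},
    {"flag": "main_bronchus", "min_t": "T2a", "citation": "AJCC7 lung: involvement of main bronchus >=2 cm distal to the carina -> at least T2"},
    {"flag": "chest_wall", "min_t": "T3", "citation": "AJCC7 lung: invasion of chest wall -> T3"},
    {"flag": "diaphragm", "min_t": "T3", "citation": "AJCC7 lung: invasion of diaphragm -> T3"},
    {"flag": "atelectasis_whole_lung", "min_t": "T3", "citation": "AJCC7 lung: atelectasis/obstructive pneumonitis of the entire lung -> T3"},
    {"flag": "separate_nodule_same_lobe", "min_t": "T3", "citation": "AJCC7 lung: separate tumor nodule(s) in the same lobe -> T3"},
    {"flag": "mediastinum", "min_t": "T4", "citation": "AJCC7 lung: invasion of mediastinum -> T4"},
    {"flag": "heart_great_vessels", "min_t": "T4", "citation": "AJCC7 lung: invasion of heart or great vessels -> T4"},
    {"flag": "carina", "min_t": "T4", "citation": "AJCC7 lung: involvement of the carina -> T4"}
  ],
  "t_multinodule_rules": [
    {"pattern": "same_lobe", "min_t": "T3", "citation": "AJCC7 lung: separate tumor nodule(s) in the same lobe -> T3"},
    {"pattern": "different_ipsilateral_lobe", "min_t": "T4", "citation": "AJCC7 lung: separate tumor nodule(s) in a different ipsilateral lobe -> T4"}
  ],
  "t_size_step_cm": 0.1,
  "n_station_levels": {
    "hilar": 1,
    "peribronchial": 1,
    "intrapulmonary": 1,
    "ipsilateral_mediastinal": 2,
    "subcarinal": 2,
    "contralateral_mediastinal": 3,
    "contralateral_hilar": 3,
    "scalene": 3,
    "supraclavicular": 3
  },
  "n_citations": {
    "1": "AJCC7 lung N1: metastasis in ipsilateral peribronchial and/or ipsilateral hilar and intrapulmonary nodes",
    "2": "AJCC7 lung N2: metastasis in ipsilateral mediastinal and/or subcarinal lymph node(s)",
    "3": "AJCC7 lung N3: metastasis in contralateral mediastinal, contralateral hilar, scalene or supraclavicular lymph node(s)"
  },
  "stage_grouping": [
    {"t": "T1a", "n": "N0", "stage": "IA"},
    {"t": "T1b", "n": "N0", "stage": "IA"},
    {"t": "T2a", "n": "N0", "stage": "IB"},
    {"t": "T2b", "n": "N0", "stage": "IIA"},
    {"t": "T1a", "n": "N1", "stage": "IIA"},
    {"t": "T1b", "n": "N1", "stage": "IIA"},
    {"t": "T2a", "n": "N1", "stage": "IIA"},
    {"t": "T2b", "n": "N1", "stage": "IIB"},
    {"t": "T3", "n": "N0", "stage": "IIB"},
    {"t": "T1a", "n": "N2", "stage": "IIIA"},
    {"t": "T1b", "n": "N2", "stage": "IIIA"},
    {"t": "T2a", "n": "N2", "stage": "IIIA"},
    {"t": "T2b", "n": "N2", "stage": "IIIA"},
    {"t": "T3", "n": "N1", "stage": "IIIA"},
    {"t": "T3", "n": "N2", "stage": "IIIA"},
    {"t": "T4", "n": "N0", "stage": "IIIA"},
    {"t": "T4", "n": "N1", "stage": "IIIA"},
    {"t": "T4", "n": "N2", "stage": "IIIB"},
    {"t": "T1a", "n": "N3", "stage": "IIIB"},
    {"t": "T1b", "n": "N3", "stage": "IIIB"},
    {"t": "T2a", "n": "N3", "stage": "IIIB"},
    {"t": "T2b", "n": "N3", "stage": "IIIB"},
    {"t": "T3", "n": "N3", "stage": "IIIB"},
    {"t": "T4", "n": "N3", "stage": "IIIB"}
  ],
  "stage_grouping_citation": "AJCC7 lung anatomic stage / prognostic groups table; any T any N with M1 -> Stage IV",
  "coarse_t_rows": {"T1": "T1a", "T2": "T2a"}
}
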