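# Charlson comorbidity conditions mapped to ICD-9-CM diagnosis codes
# (Deyo adaptation, original Charlson weights). Codes are dot-free prefixes;
# a diagnosis matches a condition when its dot-free form starts with one of
# the prefixes. "superseded_by" removes the milder condition when the more
# severe one is also present.
conditions:
  - name: myocardial_infarction
    weight: 1
    prefixes: ["410", "412"]
  - name: congestive_heart_failure
    weight: 1
    prefixes: ["428"]
  - name: peripheral_vascular_disease
    weight: 1
    prefixes: ["441", "4439", "7854", "V434"]
  - name: cerebrovascular_disease
    weight: 1
    prefixes: ["430", "431", "432", "433", "434", "435", "436", "437", "438"]
  - name: dementia
    weight: 1
    prefixes: ["290"]
  - name: chronic_pulmonary_disease
    weight: 1
    prefixes: ["490", "491", "492", "493", "494", "495", "496", "500", "501",
               "502", "503", "504", "505", "5064"]
  - name: rheumatologic_disease
    weight: 1
    prefixes: ["7100", "7101", "7104", "7140", "7141", "7142", "71481", "725"]
  - name: peptic_ulcer_disease
    weight: 1
    prefixes: ["531", "532", "533", "534"]
  - name: mild_liver_disease
    weight: 1
    prefixes: ["5712", "5714", "5715", "5716"]
    superseded_by: moderate_severe_liver_disease
  - name: diabetes
    weight: 1
    prefixes: ["2500", "2501", "2502", "2503", "2507"]
    superseded_by: diabetes_with_complications
  - name: diabetes_with_complications
    weight: 2
    prefixes: ["2504", "2505", "2506"]
  - name: hemiplegia_paraplegia
    weight: 2
    prefixes: ["342", "3441"]
  - name: renal_disease
    weight: 2
    prefixes: ["582", "5830", "5831", "5832", "5834", "5836", "5837", "585",
               "586", "5880"]
  - name: malignancy
    weight: 2
    prefixes: ["140", "141", "142", "143", "144", "145", "146", "147", "148",
               "149", "150", "151", "152", "153", "154", "155", "156", "157",
               "158", "159", "160", "161", "162", "163", "164", "165", "170",
               "171", "172", "174", "175", "176", "179", "180", "181", "182",
               "183", "184", "185", "186", "187", "188", "189", "190", "191",
               "192", "193", "194", "195", "200", "201", "202", "203", "204",
               "205", "206", "207", "208"]
    superseded_by: metastatic_solid_tumor
  - name: moderate_severe_liver_disease
    weight: 3
    prefixes: ["4560", "4561", "4562", "5722", "5723", "5724", "5728"]
  - name: metastatic_solid_tumor
    weight: 6
    prefixes: ["196", "197", "198", "1990", "1991"]
  - name: aids
    weight: 6
    prefixes: ["042", "043", "044"]
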