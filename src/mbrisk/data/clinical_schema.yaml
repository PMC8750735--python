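# Variable schema for the 31-predictor breast-cancer metastasis table.
#
# Binned-numeric variables use lower-inclusive / upper-exclusive bins; the
# final bin is unbounded above.  bin_edges list the lower edge of each bin.
# The designated missing token ("NA") maps to an extra per-column category
# at load time rather than dropping the record.
missing_token: "NA"
horizons: [5, 10, 15]
outcomes:
  - name: "metastasis_5yr"
    categories: ["no", "yes"]
  - name: "metastasis_10yr"
    categories: ["no", "yes"]
  - name: "metastasis_15yr"
    categories: ["no", "yes"]
variables:
  - name: "Race"
    categories: ["White", "Black", "Asian", "American Indian or Alaskan native", "native Hawaiian or other Pacific islander"]
  - name: "Ethnicity"
    categories: ["Not Hispanic", "Hispanic"]
  - name: "Smoking"
    categories: ["Ex-smoker", "non-smoker", "cigarettes", "chewing tobacco", "cigar"]
  - name: "Alcohol usage"
    categories: ["Moderate", "no use", "use but not otherwise specified", "former user", "heavy user"]
  - name: "Family history"
    categories: ["Cancer", "no cancer", "breast cancer", "other cancer", "cancer but not otherwise specified"]
  - name: "Age_at_diagnosis"
    kind: "binned-numeric"
    categories: ["0–49", "50–69", ">69"]
    bin_edges: [0, 50, 70]
  - name: "Menopausal_status"
    categories: ["Pre-", "post-"]
  - name: "Side"
    categories: ["Left", "right"]
  - name: "TNEG"
    categories: ["Yes", "no"]
  - name: "ER"
    categories: ["Neg", "pos", "low pos"]
  - name: "ER_percent"
    kind: "binned-numeric"
    categories: ["0–20", "20–90", "90–100"]
    bin_edges: [0, 20, 90]
  - name: "PR"
    categories: ["Neg", "pos", "low pos"]
  - name: "PR_percent"
    kind: "binned-numeric"
    categories: ["0–20", "20–90", "90–100"]
    bin_edges: [0, 20, 90]
  - name: "P53"
    categories: ["Neg", "pos", "low pos"]
  - name: "HER2"
    categories: ["Neg", "pos"]
  - name: "t_tnm_stage"
    categories: ["0", "1", "2", "3", "4", "IS", "1 mic", "X"]
  - name: "n_tnm_stage"
    categories: ["0", "1", "2", "3", "4", "X"]
  - name: "Stage"
    categories: ["0", "1", "2", "3"]
  - name: "Lymph_nodes_removed"
    kind: "binned-numeric"
    categories: ["0–11", "12–22", ">22"]
    bin_edges: [0, 12, 23]
  - name: "Lymph_nodes_positive"
    kind: "binned-numeric"
    categories: ["0", "1–8", ">8"]
    bin_edges: [0, 1, 9]
  - name: "Lymph_node_status"
    categories: ["Neg", "pos"]
  - name: "Histology"
    categories: ["Lobular", "ductal"]
  - name: "Size"
    kind: "binned-numeric"
    categories: ["0–32", "32–70", ">70"]
    bin_edges: [0, 32, 70]
  - name: "Grade"
    categories: ["1", "2", "3"]
  - name: "Invasive"
    categories: ["Yes", "no"]
  - name: "Histology2"
    categories: ["IDC", "DCIS", "ILC", "NC"]
  - name: "Invasive_tumor_location"
    categories: ["Mixed duct and lobular", "duct", "lobular", "none"]
  - name: "DCIS_level"
    categories: ["Solid", "apocrine", "cribriform", "dcis", "comedo", "papillary", "micropapillary"]
  - name: "Re_excision"
    categories: ["Yes", "no"]
  - name: "Surgical_margins"
    categories: ["Residual tumor", "no residual tumor", "no primary site surgery"]
  - name: "MRIs_60_surgery"
    categories: ["Yes", "no"]
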