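"""Bundled reference tables from a 43-vs-43 ESRD vs healthy-control
salience-network study.

These are published summary statistics, not raw data: the group-comparison
statistics (t and Cohen's d per demographic/behavioral variable), the 28
significant between-group edges with their t values, the 28 classifier
discriminative weights with node coordinates, and the clinical-variable
marginals of the patient group.  They serve two purposes:

* worked-example inputs for the effect-size, weight-selection and
  top-fraction operations (the statistics are inputs, the package recomputes
  the derived quantities from them);
* realistic default parameters for the synthetic cohort generator
  (clinical/behavioral means and SDs, group sizes, gender ratio).
"""

from __future__ import annotations

import pandas as pd

#: Group size per arm in the reference design.
N_PER_GROUP = 43

#: Gender split per arm (males, females) in the reference design.
GENDER_SPLIT = (24, 19)

# Per-variable group comparison: printed t and Cohen's d magnitude,
# n = 43 per group throughout.  d carries no sign in the source table.
GROUP_COMPARISONS = pd.DataFrame(
    [
        ("age", -0.084, 0.018),
        ("education", 1.515, 0.327),
        ("FD", -0.466, 0.101),
        ("MoCA", 3.927, 0.847),
        ("HAMD", -5.376, 1.159),
        ("HAMA", -2.702, 0.583),
        ("SDMT", 3.386, 0.730),
        ("FDST", 4.750, 1.024),
        ("BDST", 3.302, 0.712),
        ("TMT-A", -3.438, 0.742),
        ("TMT-B", -2.913, 0.628),
    ],
    columns=["variable", "t_value", "cohens_d"],
)

# The 28 edges with significantly lower patient connectivity, with the
# published edge-wise |t| (control minus patient direction).
SIGNIFICANT_EDGE_T = pd.DataFrame(
    [
        ("Anterior_insula_R", "Supramarginal_R", 4.59),
        ("Frontal_mid_R", "Cerebellum_6_L2", 4.55),
        ("Precuneus_L", "Posterior_insula_L", 4.22),
        ("dACC", "Anterior_insula_L", 4.19),
        ("Cingulum_mid_R", "Posterior_insula_L", 4.15),
        ("dACC", "Anterior_insula_R", 4.09),
        ("Cerebellum_6_L", "Cerebellum_6_R", 4.07),
        ("Anterior_insula_L", "Supramarginal_L", 4.06),
        ("Anterior_insula_L", "Posterior_insula_L", 4.06),
        ("Anterior_insula_L", "Supramarginal_R", 4.00),
        ("Cingulum_mid_R", "Posterior_insula_R", 3.93),
        ("Precuneus_L", "Cerebellum_6_L2", 3.72),
        ("Anterior_insula_L", "Cingulum_mid_R", 3.69),
        ("Cingulum_mid_R", "Cerebellum_6_L2", 3.69),
        ("Anterior_insula_R", "Supramarginal_L", 3.63),
        ("Frontal_mid_L", "Cerebellum_6_R", 3.59),
        ("Frontal_mid_L", "Cerebellum_6_L2", 3.42),
        ("Anterior_insula_L", "Anterior_insula_R", 3.41),
        ("Thalamus_L", "Thalamus_R", 3.36),
        ("Frontal_mid_L2", "Cerebellum_6_R", 3.31),
        ("Frontal_mid_L2", "Cerebellum_6_L2", 3.30),
        ("Frontal_mid_R", "Cerebellum_6_L", 3.29),
        ("Supramarginal_L", "Cerebellum_6_R", 3.28),
        ("Supramarginal_R", "Posterior_insula_L", 3.26),
        ("dACC", "Posterior_insula_L", 3.26),
        ("Frontal_mid_R", "Posterior_insula_L", 3.23),
        ("Frontal_mid_L", "Anterior_insula_L", 3.21),
        ("Frontal_mid_R", "Anterior_insula_R", 3.16),
    ],
    columns=["node_a", "node_b", "t_value"],
)

# Signed fold-averaged linear-SVM weights of the same 28 edges.
DISCRIMINATIVE_WEIGHTS = pd.DataFrame(
    [
        ("Cerebellum_6_L", "Cerebellum_6_R", -0.461),
        ("Anterior_insula_L", "Posterior_insula_L", -0.357),
        ("Cerebellum_6_L2", "Precuneus_L", -0.286),
        ("Posterior_insula_L", "Cingulum_mid_R", -0.281),
        ("Anterior_insula_R", "Anterior_insula_L", -0.264),
        ("Cerebellum_6_L2", "Frontal_mid_R", -0.233),
        ("Posterior_insula_L", "Precuneus_L", -0.226),
        ("Anterior_insula_R", "dACC", -0.216),
        ("Anterior_insula_L", "dACC", -0.212),
        ("Anterior_insula_R", "Frontal_mid_R", 0.178),
        ("Anterior_insula_R", "Supramarginal_R", -0.168),
        ("Cerebellum_6_L2", "Frontal_mid_L", -0.157),
        ("Posterior_insula_R", "Cingulum_mid_R", -0.142),
        ("Anterior_insula_L", "Supramarginal_R", -0.138),
        ("Cingulum_mid_R", "Anterior_insula_L", -0.133),
        ("Cerebellum_6_L2", "Frontal_mid_L2", -0.114),
        ("Posterior_insula_L", "dACC", 0.104),
        ("Anterior_insula_L", "Supramarginal_L", -0.095),
        ("Thalamus_R", "Thalamus_L", 0.092),
        ("Cerebellum_6_L2", "Cingulum_mid_R", -0.087),
        ("Cerebellum_6_R", "Frontal_mid_L", 0.085),
        ("Anterior_insula_L", "Frontal_mid_L", 0.070),
        ("Cerebellum_6_R", "Frontal_mid_L2", -0.067),
        ("Anterior_insula_R", "Supramarginal_L", 0.066),
        ("Posterior_insula_L", "Frontal_mid_R", 0.059),
        ("Cerebellum_6_R", "Supramarginal_L", 0.029),
        ("Posterior_insula_L", "Supramarginal_R", 0.028),
        ("Cerebellum_6_L", "Frontal_mid_R", -0.022),
    ],
    columns=["node_a", "node_b", "weight"],
)

#: Laboratory marginals of the patient group: variable -> (mean, SD).
CLINICAL_REFERENCE = {
    "serum_urea_nitrogen": (19.1, 10.2),   # mmol/L
    "serum_creatinine": (677.4, 294.1),    # umol/L
    "triglyceride": (1.9, 1.2),            # mmol/L
    "cholesterol": (4.2, 1.0),             # mmol/L
    "low_density_lipoprotein": (2.3, 0.7), # mmol/L
    "hemoglobin": (89.7, 22.3),            # g/L
}

#: Neuropsychological marginals per group: test -> {group: (mean, SD)}.
BEHAVIOR_REFERENCE = {
    "MoCA": {"control": (26.0, 3.0), "patient": (23.0, 5.0)},
    "HAMD": {"control": (4.6, 3.9), "patient": (11.5, 7.4)},
    "HAMA": {"control": (5.1, 3.5), "patient": (8.3, 7.1)},
    "SDMT": {"control": (50.0, 14.0), "patient": (41.0, 10.0)},
    "FDST": {"control": (6.9, 1.5), "patient": (5.3, 1.4)},
    "BDST": {"control": (5.9, 1.6), "patient": (4.9, 1.2)},
    "TMT-A": {"control": (56.0, 27.0), "patient": (76.0, 29.0)},
    "TMT-B": {"control": (68.0, 35.0), "patient": (97.0, 55.0)},
}

#: Demographic marginals per group: (mean, SD).
DEMOGRAPHIC_REFERENCE = {
    "age": {"control": (46.0, 10.0), "patient": (47.0, 10.0)},
    "education": {"control": (10.8, 4.1), "patient": (9.6, 3.0)},
}
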