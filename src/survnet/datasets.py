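"""Small bundled example data.

``HCC_TOP5_SUBNETWORKS`` holds the component gene lists of the five
top-ranked published prognostic subnetworks for hepatocellular carcinoma
(chemokine/extracellular-matrix and CAV1 cell-death branches).  They are
included as a worked example for :func:`survnet.reporting.merge_modules`:
subnetworks 1, 2 and 4 share FBLN2 (1 and 4 additionally VCAN, CCL21 and
XCL1) and subnetworks 3 and 5 share the CAV1/TNFRSF1B/CSNK2A2/GNAI2/MAPK3
core, so shared-gene merging collapses the five lists into exactly two
functional modules.
"""

HCC_TOP5_SUBNETWORKS: list[frozenset[str]] = [
    frozenset({"CCR7", "XCL1", "VCAN", "CCL21", "CCL19", "FBLN2"}),
    frozenset({"HIST1H2BJ", "LOX", "DPT", "BAT3", "ELN", "FBLN2", "ASS1"}),
    frozenset(
        {"PPIL2", "BSG", "MMP1", "SLC16A1", "TIMP1", "CAV1", "TNFRSF1B",
         "CSNK2A2", "GNAI2", "MAPK3"}
    ),
    frozenset({"CCR6", "CCL20", "VCAN", "FBLN2", "CCL21", "XCL1"}),
    frozenset(
        {"ACAA2", "SCP2", "ACOX1", "CAV1", "TNFRSF1B", "CSNK2A2", "GNAI2",
         "MAPK3"}
    ),
]
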