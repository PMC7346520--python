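# Scarce-drug allocation network: 3 paradigm clusters, 8 need indicators,
# controlled by a single allocation goal.
#
# NOTE: the edge set is a plausible reconstruction, not an elicited one.
# The published model diagram it is modeled on names only the outer arrow
# from Efficiency toward Equity and Access explicitly; the goal edges and
# the inner dependence within each cluster are inferred from the model
# description and from the questionnaire size.
goal: "Scarce drug allocation"
clusters:
  - name: "Efficiency"
    elements:
      - "Total population"
      - "Non-resident patient"
  - name: "Equity and Access"
    elements:
      - "Number of health professionals"
      - "Total bed occupancy rate"
      - "Number of prescriptions"
  - name: "Effectiveness"
    elements:
      - "Burden of endemic diseases"
      - "Burden of special, rare and incurable diseases"
      - "Burden of traumatic diseases"
dependencies:
  - {source: "Scarce drug allocation", target_cluster: "Efficiency", kind: outer}
  - {source: "Scarce drug allocation", target_cluster: "Equity and Access", kind: outer}
  - {source: "Scarce drug allocation", target_cluster: "Effectiveness", kind: outer}
  - {source: "Efficiency", target_cluster: "Equity and Access", kind: outer}
  - {source: "Efficiency", target_cluster: "Efficiency", kind: inner}
  - {source: "Equity and Access", target_cluster: "Equity and Access", kind: inner}
  - {source: "Effectiveness", target_cluster: "Effectiveness", kind: inner}
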