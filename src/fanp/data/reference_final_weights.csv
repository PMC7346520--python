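# Reported final weights of the scarce-drug allocation study this package's
# worked example comes from. Shipped for side-by-side comparison only: they
# derive from elicited supermatrices that are not part of the bundled inputs,
# so they are NOT recomputation targets of this package.
# The third Effectiveness row is labeled "Burden of traumatic diseases" here;
# the published table repeats the special/rare label for it by an apparent typo.
cluster,element,within_cluster_weight,overall_weight,cluster_weight,cluster_rank
Efficiency,Total population,0.6942,0.211,0.370,2
Efficiency,Non-resident patient,0.3065,0.075,0.370,2
Equity and Access,Number of health professionals,0.1727,0.046,0.459,1
Equity and Access,Total bed occupancy rate,0.3833,0.190,0.459,1
Equity and Access,Number of prescriptions,0.4451,0.262,0.459,1
Effectiveness,Burden of endemic diseases,0.3418,0.053,0.171,3
Effectiveness,Burden of special rare and incurable diseases,0.3754,0.077,0.171,3
Effectiveness,Burden of traumatic diseases,0.2846,0.068,0.171,3
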