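"""Analyze one target/reference gene pair from a Cq table.

A minimal end-to-end run: read a delimited Cq table, fit the mixed model,
and compare the naive (unit-efficiency), plug-in (EC) and variance-adjusted
(ECVA1/ECVA2) tests of the delta-delta-Cq contrast.
"""

import io

from ddcq import ModelSpec, analyze, fit_lmm, read_cq_table, results_frame

# Six case and six control samples measured for a target (TAR) and a
# reference (REF) gene, plus one standard-curve sample diluted 2-fold six
# times for each gene.  In a real analysis this would be a file path.
TABLE = """gene_id,gene_role,sample_group,sample_id,dilution_steps,cq
TAR,target,case,c1,0,26.45
TAR,target,case,c2,0,28.91
TAR,target,case,c3,0,25.10
TAR,target,case,c4,0,26.70
TAR,target,case,c5,0,27.35
TAR,target,case,c6,0,25.95
REF,reference,case,c1,0,24.89
REF,reference,case,c2,0,26.70
REF,reference,case,c3,0,23.85
REF,reference,case,c4,0,25.05
REF,reference,case,c5,0,25.60
REF,reference,case,c6,0,24.40
TAR,target,control,u1,0,25.25
TAR,target,control,u2,0,24.32
TAR,target,control,u3,0,26.10
TAR,target,control,u4,0,25.55
TAR,target,control,u5,0,23.90
TAR,target,control,u6,0,25.05
REF,reference,control,u1,0,24.95
REF,reference,control,u2,0,23.95
REF,reference,control,u3,0,25.80
REF,reference,control,u4,0,25.30
REF,reference,control,u5,0,23.60
REF,reference,control,u6,0,24.70
TAR,target,standard,std,1,26.44
TAR,target,standard,std,2,27.75
TAR,target,standard,std,3,28.80
TAR,target,standard,std,4,30.25
TAR,target,standard,std,5,31.51
TAR,target,standard,std,6,32.60
REF,reference,standard,std,1,25.67
REF,reference,standard,std,2,26.84
REF,reference,standard,std,3,27.75
REF,reference,standard,std,4,28.73
REF,reference,standard,std,5,29.84
REF,reference,standard,std,6,30.94
"""

ds = read_cq_table(io.StringIO(TABLE))

# Look at the fitted model itself first
fit = fit_lmm(ds, ModelSpec())
print("estimated inverse log2-efficiencies (standard-curve slopes):")
for role, g in sorted(fit.theta.gamma.items()):
    print(f"  gamma[{role}] = {g:.3f}  (AE = {2 ** (1 / g):.3f})")
print(f"sample variance sigma_S^2 = {fit.sigma_S2:.3f}, "
      f"residual df = {fit.df_residual:g}\n")

# One table row per method; all EC-family point estimates coincide, only
# the standard errors (and hence p-values and intervals) differ.
results = analyze(ds, methods=("naive", "EC", "ECVA1", "ECVA2"), seed=1)
print(results_frame(results).to_string(index=False))
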