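"""One virtual patient through all three treatment arms.

Builds a TMB-high, PD-L1-high MSS CRC patient, grows the tumor to its
pre-treatment size, then simulates atezolizumab 1200 mg Q3W, cibisatamab
60 mg QW and their combination to day 400, printing the RECIST outcome
of each arm.
"""

from qspvct import ModelParams, initialize_pretreatment, simulate_patient
from qspvct.model_core import pretreatment_observables
from qspvct.trial_engine import classify_recist, default_arms

patient = ModelParams(
    n_clones=100.0,      # TMB: activatable T-cell clones
    pdl1_cancer=6.0e4,   # sites/cell; strong checkpoint cover pre-treatment
    cea_total=1.0e5,     # CEA density on the cancer cell
    lam=4.0,             # cibisatamab cross-arm efficiency
)

pre = initialize_pretreatment(patient)
obs = pretreatment_observables(pre, patient)
print("pre-treatment state (tumor grown to target size without drug):")
for k, v in obs.items():
    print(f"  {k}: {v:.4g}")

for arm in default_arms():
    traj = simulate_patient(patient, arm.regimens, pre_state=pre)
    cls, pct = classify_recist(obs["tumor_diameter_cm"],
                               float(traj.diameter_cm[-1]))
    print(f"{arm.arm_id:>18}: day-400 diameter "
          f"{traj.diameter_cm[-1]:6.2f} cm ({pct:+6.1f} %) -> {cls}")
print("-> the engager alone only stabilizes this checkpoint-suppressed"
      "\n   lesion; blockade alone shrinks it; together they clear it.")
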