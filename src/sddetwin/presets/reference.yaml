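# Version-pinned default parameter preset for the four-variable cascade.
# Calibrated once with scripts/calibrate_preset.py and then frozen; do not
# edit in place — add a new preset file instead (outputs embed this file's
# content hash).
#
# Design notes (see docs/methods.md for the full account):
# * The dominant stochasticity is the multiplicative neutrophil noise
#   (sigma1) acting during a short, strong stressor pulse: each subject
#   acquires an effectively scalar inflammatory gain; downstream noise
#   intensities are kept small so trajectories are smooth.
# * The latent output Y integrates the imbalance beta1*B2 - beta2*B3 with
#   no self-decay (beta3 = 0): its peak marks the time the regulatory arm
#   overtakes the pro-inflammatory arm.
# * Two competing crests shape time-to-peak: an early crest while the
#   delayed albumin dip transiently relieves suppression, and a late crest
#   when the long-lagged CRP surge (tau7) arrives against recovering
#   albumin. Which crest wins grows with the subject's gain, linking
#   delayed peaks to high peaks.
name: reference
alpha1: 1.0     # stressor -> neutrophil gain
alpha2: 1.8     # neutrophil clearance (fast arm)
gamma1: 0.25    # neutrophil -> CRP induction
gamma2: 0.25    # CRP clearance (intermediate arm)
theta1: 0.8     # albumin baseline production
theta2: 2.0     # CRP -> albumin suppression
theta3: 0.05    # albumin relaxation (slow arm; equilibrium theta1/theta3)
beta1: 0.2      # CRP -> Y gain
beta2: 0.02     # albumin -> Y suppression
beta3: 0.0      # Y self-decay (pure imbalance integrator)
sigma1: 0.8     # neutrophil noise: the subject-level gain heterogeneity
sigma2: 0.0005
sigma3: 0.0005
sigma4: 0.0005
tau1: 0.5       # stress -> neutrophil activation lag
tau2: 0.5       # neutrophil self-regulation lag
tau3: 2.0       # neutrophil -> CRP induction lag
tau4: 2.0       # CRP self-regulation lag
tau5: 2.0       # CRP -> albumin suppression lag
tau6: 2.0       # albumin self-regulation lag
tau7: 24.0      # CRP -> clinical output propagation lag
tau8: 0.5       # albumin -> clinical output lag
tau9: 2.0       # output self-regulation lag
baseline_b1: 0.1
baseline_b2: 1.0   # pre-stress CRP tone (relaxes toward equilibrium)
baseline_b3: 16.0  # albumin equilibrium theta1/theta3
baseline_y: 0.0
stressor:
  amplitude: 10.5
  onset: 1.0
  duration: 0.8
grid:
  t0: 0.0
  t_end: 100.0
  dt: 0.01
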