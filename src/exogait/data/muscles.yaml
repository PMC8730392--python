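# Default parameter table for the 9 merged sagittal-plane muscles (one leg).
# Version 1.  Merging rule for anatomical sub-heads: summed f_max, averaged
# optimal fiber length and tendon slack length.  Nominal values follow the
# conventions of lower-limb Hill-model tables for a ~75 kg adult; they are
# the pre-calibration defaults and are overridable via this file's schema.
# Units: f_max N, lengths m, pennation rad, v_max optimal fiber lengths/s.
muscles:
  glut_max:
    f_max: 3000.0
    l_m_opt: 0.14
    l_t_slack: 0.10
    pennation_opt: 0.35
    fast_twitch_fraction: 0.45
  hamstrings:
    f_max: 2500.0
    l_m_opt: 0.10
    l_t_slack: 0.31
    pennation_opt: 0.20
    fast_twitch_fraction: 0.45
  iliopsoas:
    f_max: 2200.0
    l_m_opt: 0.11
    l_t_slack: 0.12
    pennation_opt: 0.22
    fast_twitch_fraction: 0.50
  rect_fem:
    f_max: 1200.0
    l_m_opt: 0.08
    l_t_slack: 0.32
    pennation_opt: 0.24
    fast_twitch_fraction: 0.55
  vasti:
    f_max: 5000.0
    l_m_opt: 0.09
    l_t_slack: 0.21
    pennation_opt: 0.29
    fast_twitch_fraction: 0.50
  bifemsh:
    f_max: 800.0
    l_m_opt: 0.11
    l_t_slack: 0.10
    pennation_opt: 0.40
    fast_twitch_fraction: 0.55
  gastroc:
    f_max: 2500.0
    l_m_opt: 0.06
    l_t_slack: 0.38
    pennation_opt: 0.30
    fast_twitch_fraction: 0.55
  soleus:
    f_max: 3500.0
    l_m_opt: 0.05
    l_t_slack: 0.25
    pennation_opt: 0.44
    fast_twitch_fraction: 0.20
  tib_ant:
    f_max: 1200.0
    l_m_opt: 0.07
    l_t_slack: 0.22
    pennation_opt: 0.17
    fast_twitch_fraction: 0.30
# Anatomical sagittal-plane DOF spans (storage DOFs: hip_flexion,
# knee_flexion, ankle_dorsiflexion; all angles positive in flexion /
# dorsiflexion).
spans:
  glut_max: [hip_flexion]
  hamstrings: [hip_flexion, knee_flexion]
  iliopsoas: [hip_flexion]
  rect_fem: [hip_flexion, knee_flexion]
  vasti: [knee_flexion]
  bifemsh: [knee_flexion]
  gastroc: [knee_flexion, ankle_dorsiflexion]
  soleus: [ankle_dorsiflexion]
  tib_ant: [ankle_dorsiflexion]
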