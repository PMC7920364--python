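# Dimensional model parameters for the transwell tumor/neutrophil model.
# Version 1.  Units as noted; ranged literature entries are recorded with
# their range and the default used by tanwell.
#   - mu_ED was published as a range (2.8e-4 .. 2.8e-2 1/s): default = the
#     upper end, the regime consistent with near-complete NE suppression
#     under DNase I.
#   - mu_PM was published as a range (2.8e-5 .. 2.8e-4 1/s): default = the
#     upper end, which is the regime consistent with the strong (~80%)
#     MMP knockdown the TIMP experiment exhibits.
#   - gamma_cells / gamma_mol were published dimensionless as ranges
#     0.01-785 (78.5) and 0.1-7850 (785): defaults = parenthesized values.
diffusion:           # cm^2/s
  D_n:   2.5e-8      # tumor cells
  D_N1:  1.1e-8      # N1 neutrophils
  D_N2:  1.1e-8      # N2 neutrophils
  D_C:   2.5e-6      # CXCL8
  D_G:   1.0e-6      # TGF-beta
  D_E:   5.0e-7      # NET/NE
  D_P:   5.0e-10     # MMP
  D_D:   7.374e-6    # DNase I (NE inhibitor)
  D_M:   8.33e-7     # TIMP
  D_A:   8.33e-7     # TGF-beta antibody
production:
  r:     3.3e-4      # 1/s, tumor proliferation
  r_E:   7.0e-2      # dimensionless, NE-boosted proliferation amplitude
  k_E:   2.15e-9     # g/cm^3, Hill half-saturation of the NE growth boost
  m_E:   2           # Hill exponent (NE growth boost)
  n_cap: 2.5e4       # cells/cm^3, tumor carrying capacity
  lam_1: 4.38e-6     # 1/s, N1 proliferation
  lam_12: 4.08e3     # cm^3/(g s), TGF-beta-driven N1->N2 transition
  lam_2: 2.65e-5     # 1/s, N2 proliferation
  lam_C: 4.44e-11    # 1/s, CXCL8 secretion by tumor cells
  lam_G: 4.89e-7     # 1/s, TGF-beta secretion by tumor cells
  lam_E: 2.26e-7     # 1/s, NET/NE production by N2
  lam_P: 2.22e-8     # 1/s, MMP production by N2
  lam_D: 9.0e-13     # g/(cm^3 s), DNase supply on the injection region
  lam_M: 1.29e-11    # g/(cm^3 s), TIMP supply
  lam_A: 4.78e-5     # uM/s, antibody supply
decay:
  mu_n:   2.78e-1    # cm^3/(g s), tumor killing by N1
  mu_rho1: 1.02e4    # cm^3/(g s), ECM degradation by NE
  mu_rho2: 3.19e5    # cm^3/(g s), ECM degradation by MMP
  mu_C:   6.42e-5    # 1/s
  mu_G:   8.02e-6    # 1/s
  mu_E:   8.02e-6    # 1/s
  mu_P:   5.0e-5     # 1/s
  mu_D:   9.627e-5   # 1/s
  mu_M:   4.56e-6    # 1/s
  mu_ED:  2.8e-2     # 1/s, NE consumption by DNase (range 2.8e-4..2.8e-2)
  mu_A:   6.42e-5    # 1/s
  mu_AG:  4.8e-3     # 1/(uM s), TGF-beta consumption by antibody
  K_D:    3.2e-9     # g/cm^3, Hill constant of NE inhibition
  l_D:    2          # Hill exponent (NE inhibition)
  mu_PM:  2.8e-4     # 1/s, MMP degradation by TIMP (range 2.8e-5..2.8e-4)
  K_M:    4.64e-8    # g/cm^3, Hill constant of MMP inhibition
  m_M:    2          # Hill exponent (MMP inhibition)
taxis:
  chi_E:     1.117e-9   # cm/s, tumor chemotaxis to NE
  delta_E:   6.46e-8    # g/cm^4
  sigma_E:   1.0
  chi_rho:   3.5e-10    # cm/s, tumor haptotaxis on ECM
  delta_rho: 5.0e-3     # g/cm^4
  sigma_rho: 1.0
  chi_N1:    1.1e-9     # cm/s, N1 chemotaxis to CXCL8
  delta_N1:  1.0e-11    # g/cm^4
  chi_N2:    1.1e-9     # cm/s, N2 chemotaxis to CXCL8
  delta_N2:  1.0e-11    # g/cm^4
  sigma_C:   1.0
membrane:              # dimensionless permeabilities
  gamma_cells: 78.5    # tumor cells and neutrophils (range 0.01-785)
  gamma_mol:   785.0   # diffusible molecules (range 0.1-7850)
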