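# Default parameterisation of the DEHA/MEHA physiologically based biokinetic
# model. Units are encoded in key suffixes. Volume fractions are fractions of
# body weight; flow fractions are fractions of cardiac output. Half-lives are
# in minutes and are converted to clearances (L/h) at parameter assembly.
physiology:
  BW_kg: 89.0
  VT_frac: 0.95            # total vascularised fraction of body weight
  VLiC_frac: 0.0309        # liver
  VFaC_frac: 0.195         # adipose
  VGuC_frac: 0.015         # gut
  VStC_frac: 0.0022        # stomach
  VSpdC_frac: 0.607        # slowly perfused tissue
  VRpdC_frac: 0.0371       # rapidly perfused tissue
  VBldC_frac: 0.05         # blood
  QCC_L_per_h_per_kg: 14.0 # cardiac output per kg body weight
  QHepartC_frac: 0.060     # hepatic-artery share of cardiac output
  QFaC_frac: 0.050
  QGuC_frac: 0.149
  QStC_frac: 0.011
  QSpdC_frac: 0.270
  QRpdC_frac: 0.420

partitions:
  logP_DEHA: 9.54          # predicted octanol-water log partition coefficient
  logP_MEHA: 5.84
  # fu values are the algorithmic predictions from logP (reference only; the
  # operative binding parameters are FB_DEHA / FB_MEHA below).
  fu_DEHA: 0.000158
  fu_MEHA: 0.007175
  FB_DEHA: 0.90            # bound fraction in arterial blood
  FB_MEHA: 0.90
  # tissue:blood partition coefficients, DEHA
  Pbab: 3.0                # blood-cell/plasma reservoir
  Pfab: 47.2               # adipose
  Plib: 5.9                # liver
  Pgub: 7.4                # gut
  Pstb: 7.4                # stomach (surrogate: gut)
  Prpdb: 3.7               # rapidly perfused (surrogate: spleen)
  Pspdb: 3.3               # slowly perfused (surrogate: muscle)
  # tissue:blood partition coefficients, MEHA
  PbaM: 1.23
  PfaM: 2.00
  PliM: 10.7
  PguM: 3.08
  PstM: 3.08
  PrpdM: 2.26
  PspdM: 1.83

kinetics:
  # metabolic clearance inputs (in vitro / in vivo half-lives, minutes)
  T_half_DEHA_min: 3.0         # hepatic; see priors.yaml note on this value
  T_half_DEHA_gut_min: 30.0    # gut
  T_half_MEHA_min: 22.8        # hepatic, from microsomal incubations
  MPY_mg_per_g: 34.0           # hepatic microsomal protein yield
  MPY_gut_mg_per_g: 3.9        # gut microsomal protein yield
  protein_conc_mg_per_ml: 0.5  # incubation microsomal protein concentration
  tissue_density_g_per_ml: 1.05
  # oral uptake
  FracAbsorbed: 0.627          # fraction of ingested dose absorbed
  FracDOSEHep: 0.503           # absorbed fraction taken up via the portal route
  BELLYPERM_per_h: 3.72        # first-order stomach absorption
  GIPERM_per_h: 14.79          # first-order intestinal absorption
  k_gastric_emptying_per_h: 1.0
  Lymphlag_h: 2.99             # lymphatic transport delay
  K1_Lymph_per_h: 2.54         # lymph-to-venous-blood transfer
  # urinary metabolite pools
  FracMetab_OH: 0.00089        # fraction of metabolised MEHA to 5OH-MEHA pool
  FracMetab_cx: 0.00375        # fraction of metabolised MEHA to 5cx-MEPA pool
  K1_OH_per_h: 2.72            # blood-to-urine elimination, 5OH-MEHA
  K1_cx_per_h: 2.72            # blood-to-urine elimination, 5cx-MEPA

# Molar masses computed from molecular formulae.
molar_masses:
  M_DEHA_g_per_mol: 370.57     # C22H42O4
  M_MEHA_g_per_mol: 258.36     # C14H26O4
  M_5OH_g_per_mol: 274.35      # C14H26O5
  M_5cx_g_per_mol: 288.34      # C14H24O6
  M_5oxo_g_per_mol: 272.34     # C14H24O5
  M_AA_g_per_mol: 146.14       # C6H10O4, adipic acid
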