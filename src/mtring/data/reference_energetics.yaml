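# Published per-ring MM/GBSA interaction energies for 13-protofilament
# microtubule ring models with GDP or GTP at the exchangeable site, used as
# worked-example fixtures.  All energies are kcal/mol per MT ring; "sd" values
# are the published snapshot standard deviations.
#
# Subunit/role matrices: cell "L_beta" is the contribution of the beta subunit
# of the dimer acting as ligand, etc.
subunit_matrix:
  lateral:
    GDP:
      cells: {L_beta: -25.0, R_beta: -147.0, L_alpha: -165.0, R_alpha: -74.0}
      sd: {L_beta: 14.0, R_beta: 15.0, L_alpha: 14.0, R_alpha: 15.0}
      grand_sd: 29.0
    GTP:
      cells: {L_beta: -61.0, R_beta: -145.0, L_alpha: -193.0, R_alpha: -83.0}
      sd: {L_beta: 14.0, R_beta: 16.0, L_alpha: 15.0, R_alpha: 14.0}
      grand_sd: 29.0
  longitudinal:
    GDP:
      cells: {L_beta: -664.0, R_beta: 0.0, L_alpha: 0.0, R_alpha: -576.0}
      sd: {L_beta: 24.0, R_beta: 0.0, L_alpha: 0.0, R_alpha: 21.0}
      grand_sd: 32.0
    GTP:
      cells: {L_beta: -623.0, R_beta: 0.0, L_alpha: 0.0, R_alpha: -475.0}
      sd: {L_beta: 22.0, R_beta: 0.0, L_alpha: 0.0, R_alpha: 20.0}
      grand_sd: 30.0
# Component groupings E(vdW+SA) and E(ele+GB), per ring.
components:
  lateral:
    GDP: {vdw_sa: -1476.0, ele_gb: 1065.0}
    GTP: {vdw_sa: -1432.0, ele_gb: 950.0}
  longitudinal:
    GDP: {vdw_sa: -2668.0, ele_gb: 1428.0}
# Radial profile outward sums (x beyond the tubulin center of mass, ~30 A
# from the lumen) across the longitudinal inter-dimer interface, per ring.
radial_outward:
  GDP: -982.0
  GTP: -956.0
# Tangential profile right-side sums (x beyond the center of mass, toward the
# nucleotide-binding domain), per ring.
tangential_right:
  GDP: -887.0
  GTP: -1023.0
# Per-interface lateral energies in the GDP model: the seam (dimer 13 against
# the periodic image of dimer 1) and the strongest-contrast neighbor printed
# alongside it (dimers 12-13).
lateral_interfaces:
  GDP:
    seam: {energy: -9.0, sd: 7.0}
    lateral_12: {energy: -57.0, sd: 9.0}
# Exchangeable-site cofactor bookkeeping (GTP model minus GDP model):
# swapping GDP for GTP changes the cofactor contribution by about -125, while
# the accompanying Mg2+ ion adds +95 of destabilization.
esite:
  cofactor_gtp_minus_gdp: {energy: -125.0, sd: 14.0}
  mg_destabilization: {energy: 95.0, sd: 4.0}
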