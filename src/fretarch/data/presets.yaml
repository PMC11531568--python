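# Named photophysical and dye-geometry presets.
#
# cy3b_T / cy3b_H: Cy3B donor paired with ATTO 647N, with the donor lifetime
# measured on the two single-cysteine InlB_321 label-site variants
# (T = residue 280, H = residue 64).  k_F in ns^-1, tau_L in ns, J in
# M^-1 cm^-1 nm^4.
fluorophore_pairs:
  cy3b_T:
    k_F: 0.239
    tau_L: 2.6
    kappa2: 0.6666666666666666
    n_refr: 1.34
    J: 5.8e15
  cy3b_H:
    k_F: 0.239
    tau_L: 2.5
    kappa2: 0.6666666666666666
    n_refr: 1.34
    J: 5.8e15

# Accessible-volume dye/linker geometries (Å).  The linker is a cylinder
# (length = height, width = diameter); the dye is an ellipsoid approximated
# by three radii (3AV model).
dyes:
  atto647n_maleimide:
    linker_length: 21.0
    linker_width: 4.5
    dye_radii: [7.15, 4.5, 1.5]
  cy3b_maleimide:
    linker_length: 18.5
    linker_width: 4.5
    dye_radii: [3.4, 8.2, 3.0]

# SMLM camera-pixel ceilings applied to NeNA-derived radii.
smlm:
  pixel_size_nm: 157.0
  link_radius_max_px: 0.45   # ceiling on the 6*NeNA linking radius
  dbscan_eps_max_px: 0.15    # ceiling on the 2*NeNA DBSCAN radius
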