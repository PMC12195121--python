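# Versioned footprint fraction table (fractions of the reference-frame
# extents).  Femoral depth is measured from the POSTERIOR border of the
# quadrant grid; set femoral_depth_from: anterior to use the opposite
# convention.  The central bundle is derived as the midpoint of the AM and
# PL surface points and therefore carries no fractions of its own.
version: 1
femoral_depth_from: posterior
femur:
  AM: {height: 0.25, depth: 0.33}
  PL: {height: 0.451, depth: 0.50}
tibia:
  AM: {depth: 0.35, width: 0.505}
  PL: {depth: 0.464, width: 0.524}
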