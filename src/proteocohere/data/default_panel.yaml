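# Default 41-subunit proteasome gene panel.
#
# The 26S proteasome = 20S catalytic core (alpha + beta rings) + 19S regulatory
# particle (ATPase base, non-ATPase base, lid) plus assembly chaperones and the
# PA28/PA200 activator family.  Published subunit rosters vary in whether the
# tissue-specific subunits (PSMA8, immunoproteasome betas) are counted; the exact
# 41-member list this panel reconstructs is not uniquely determined by any single
# roster, so this file is a documented best reconstruction and is fully
# overridable: pass your own YAML/JSON with the same `symbols:` mapping.
#
# Roles: alpha | beta | base_ATPase | base_nonATPase | lid | assembly | activator
symbols:
  PSMA1: alpha
  PSMA2: alpha
  PSMA3: alpha
  PSMA4: alpha
  PSMA5: alpha
  PSMA6: alpha
  PSMA7: alpha
  PSMB1: beta
  PSMB2: beta
  PSMB3: beta
  PSMB4: beta
  PSMB5: beta
  PSMB6: beta
  PSMB7: beta
  PSMB8: beta
  PSMB9: beta
  PSMB10: beta
  PSMC1: base_ATPase
  PSMC2: base_ATPase
  PSMC3: base_ATPase
  PSMC4: base_ATPase
  PSMC5: base_ATPase
  PSMC6: base_ATPase
  PSMD1: base_nonATPase
  PSMD2: base_nonATPase
  PSMD3: lid
  PSMD4: base_nonATPase
  PSMD5: assembly
  PSMD6: lid
  PSMD7: lid
  PSMD8: lid
  PSMD9: assembly
  PSMD10: assembly
  PSMD11: lid
  PSMD12: lid
  PSMD13: lid
  PSMD14: lid
  PSME1: activator
  PSME2: activator
  PSME3: activator
  PSME4: activator
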