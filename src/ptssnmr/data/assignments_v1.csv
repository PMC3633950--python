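shift_ppm,moiety,component_class,multiplicity,source,notes
14.6,omega CH3,lipid_chain,3,main_text,terminal methyl of the hydrocarbon chains
23.3,(omega-1) CH2,lipid_chain,2,main_text,penultimate methylene of the hydrocarbon chains
30.5,(CH2)n trans/gauche,lipid_chain,2,main_text,main-chain methylene with liquid-like trans/gauche distribution
32.7,(omega-2) CH2,lipid_chain,2,main_text,antepenultimate methylene of the hydrocarbon chains
33.4,(CH2)n all-trans,lipid_chain,2,main_text,main-chain methylene in crystalline all-trans conformation
40.6,Leu C_beta + Lys C_epsilon,keratin_core,2,main_text,compound peak; marker of the coiled-coil filament core
40.65,cholesterol C24/C12,cholesterol,2,fig3_caption,mobile cholesterol marker; 40.4-40.9 ppm band
42.8,cholesterol C4,cholesterol,2,main_text,mobile cholesterol marker
43.7,Gly C_alpha,keratin_terminal,2,main_text,glycine-rich terminal-domain marker; shift reference (alpha-glycine)
51.8,cholesterol C9,cholesterol,1,main_text,mobile cholesterol marker
56.7,Ser C_alpha,keratin_terminal,1,main_text,serine-rich terminal-domain marker
57.6,cholesterol C14/C17,cholesterol,1,main_text,mobile cholesterol marker
58.8,keratin C_alpha region,keratin_core,1,fig4_caption,helical C_alpha envelope centred around 57-59 ppm
62.4,Ser C_beta,keratin_terminal,2,main_text,serine hydroxymethyl; first terminal marker to hydrate
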