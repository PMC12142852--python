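# Bundled taxonomy-registry fixture: taxid <tab> scientific_name <tab> rank <tab> submittable
# Records 543, 218034, 77133 and 115547 carry their genuine public taxonomy
# identifiers. Entries with ids in the 990000xxx range are synthetic stand-ins
# for registry records whose real identifiers were not available offline.
543	Enterobacteriaceae	family	false
218034	uncultured Enterobacteriaceae bacterium	species	true
77133	uncultured bacterium	species	true
115547	uncultured archaeon	species	true
2184	Methanococcus	genus	false
990000001	uncultured Methanococcus sp.	species	true
990000002	uncultured Pseudomonadota bacterium	species	true
990000003	uncultured Escherichia sp.	species	true
990000004	uncultured Enterobacteriaceae bacterium HK-1	species	false
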