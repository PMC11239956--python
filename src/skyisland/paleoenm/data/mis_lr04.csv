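name,start_ky,end_ky,type
MIS1,0,14,interglacial
MIS2,14,29,glacial
MIS3,29,57,interglacial
MIS4,57,71,glacial
MIS5,71,130,interglacial
MIS6,130,191,glacial
MIS7,191,243,interglacial
MIS8,243,300,glacial
MIS9,300,337,interglacial
MIS10,337,374,glacial
MIS11,374,424,interglacial
MIS12,424,478,glacial
MIS13,478,533,interglacial
MIS14,533,563,glacial
MIS15,563,621,interglacial
MIS16,621,676,glacial
MIS17,676,712,interglacial
MIS18,712,761,glacial
MIS19,761,790,interglacial
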