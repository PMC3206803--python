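taxon_id	name	rank	status	accepted_id	kingdom	phylum	class	order	family	genus	species
r01	Animalia	kingdom	valid	r01	Animalia
r02	Chordata	phylum	valid	r02	Animalia	Chordata
r03	Actinopterygii	class	valid	r03	Animalia	Chordata	Actinopterygii
r04	Perciformes	order	valid	r04	Animalia	Chordata	Actinopterygii	Perciformes
r05	Pomacentridae	family	valid	r05	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae
r06	Amphiprion	genus	valid	r06	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Amphiprion
r07	Chromis	genus	valid	r07	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Chromis
r08	Mollusca	phylum	valid	r08	Animalia	Mollusca
r09	Gastropoda	class	valid	r09	Animalia	Mollusca	Gastropoda
r10	Littorinimorpha	order	valid	r10	Animalia	Mollusca	Gastropoda	Littorinimorpha
r11	Strombidae	family	valid	r11	Animalia	Mollusca	Gastropoda	Littorinimorpha	Strombidae
r12	Strombus	genus	valid	r12	Animalia	Mollusca	Gastropoda	Littorinimorpha	Strombidae	Strombus
r13	Plantae	kingdom	valid	r13	Plantae
r14	Tracheophyta	phylum	valid	r14	Plantae	Tracheophyta
r15	Liliopsida	class	valid	r15	Plantae	Tracheophyta	Liliopsida
r16	Alismatales	order	valid	r16	Plantae	Tracheophyta	Liliopsida	Alismatales
r17	Zosteraceae	family	valid	r17	Plantae	Tracheophyta	Liliopsida	Alismatales	Zosteraceae
r18	Zostera	genus	valid	r18	Plantae	Tracheophyta	Liliopsida	Alismatales	Zosteraceae	Zostera
r19	Chromista	kingdom	valid	r19	Chromista
r20	Ochrophyta	phylum	valid	r20	Chromista	Ochrophyta
r21	Phaeophyceae	class	valid	r21	Chromista	Ochrophyta	Phaeophyceae
r22	Laminariales	order	valid	r22	Chromista	Ochrophyta	Phaeophyceae	Laminariales
r23	Laminariaceae	family	valid	r23	Chromista	Ochrophyta	Phaeophyceae	Laminariales	Laminariaceae
r24	Macrocystis	genus	valid	r24	Chromista	Ochrophyta	Phaeophyceae	Laminariales	Laminariaceae	Macrocystis
r25	Amphiprion percula	species	valid	r25	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Amphiprion	Amphiprion percula
r26	Amphiprion clarkii	species	valid	r26	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Amphiprion	Amphiprion clarkii
r27	Chromis viridis	species	valid	r27	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Chromis	Chromis viridis
r28	Strombus gigas	species	valid	r28	Animalia	Mollusca	Gastropoda	Littorinimorpha	Strombidae	Strombus	Strombus gigas
r29	Strombus alatus	species	valid	r29	Animalia	Mollusca	Gastropoda	Littorinimorpha	Strombidae	Strombus	Strombus alatus
r30	Zostera marina	species	valid	r30	Plantae	Tracheophyta	Liliopsida	Alismatales	Zosteraceae	Zostera	Zostera marina
r31	Zostera muelleri	species	valid	r31	Plantae	Tracheophyta	Liliopsida	Alismatales	Zosteraceae	Zostera	Zostera muelleri
r32	Macrocystis pyrifera	species	valid	r32	Chromista	Ochrophyta	Phaeophyceae	Laminariales	Laminariaceae	Macrocystis	Macrocystis pyrifera
r33	Amphiprion ocellaris	species	valid	r33	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Amphiprion	Amphiprion ocellaris
r34	Chromis atripectoralis	species	valid	r34	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Chromis	Chromis atripectoralis
r35	Zostera noltei	species	valid	r35	Plantae	Tracheophyta	Liliopsida	Alismatales	Zosteraceae	Zostera	Zostera noltei
r36	Anthias perculus	species	synonym	r25	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Amphiprion	Anthias perculus
r37	Strombus goliath	species	synonym	r28	Animalia	Mollusca	Gastropoda	Littorinimorpha	Strombidae	Strombus	Strombus goliath
r38	Zostera nana	species	synonym	r31	Plantae	Tracheophyta	Liliopsida	Alismatales	Zosteraceae	Zostera	Zostera nana
r39	Macrocystis angustifolia	species	synonym	r32	Chromista	Ochrophyta	Phaeophyceae	Laminariales	Laminariaceae	Macrocystis	Macrocystis angustifolia
r40	Chromis caerulea	species	synonym	r27	Animalia	Chordata	Actinopterygii	Perciformes	Pomacentridae	Chromis	Chromis caerulea
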