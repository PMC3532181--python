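mirna	dG_bind	dG_flank3	dG_flank5	position	seed
miR-122	-22.0	-14.9	-11.2	671-692	partially (1-6)
miR-199a-3p	-32.1	-9.1	-14.1	76-97	no
miR-199a-3p	-30.7	-11.1	-6.9	535-556	no
miR-199a-3p	-24.3	-9.2	-6.9	705-726	no
miR-199a-3p	-22.0	-7.6	-11.3	259-280	no
miR-199a-3p	-20.5	-10.1	-6.6	26-47	no
miR-320a	-24.6	-10.9	-7.1	117-138	partially (1-5, 7-12)
miR-320a	-21.7	-6.9	-11.1	536-557	partially (1-2, 4-8)
miR-320a	-24.8	-12.3	-11.4	505-526	partially (1-4, 7-8)
miR-320a	-25.5	-6.9	-12.9	229-250	no
miR-320a	-20.5	-8.5	-5.3	711-732	no
miR-320b	-24.6	-10.9	-7.1	117-138	partially (1-5, 7-12)
miR-320b	-21.7	-6.9	-11.1	536-557	partially (1-2, 4-8)
miR-320b	-25.8	-12.3	-11.4	505-526	partially (1-4, 7-8)
miR-320b	-25.5	-6.9	-12.9	229-250	no
miR-320c	-23.2	-6.9	-12.9	230-249	no
miR-320c	-23.3	-12.3	-11.4	507-526	partially (1-4, 7-8)
miR-320c	-19.5	-7.7	-5.3	713-732	no
miR-320d	-24.4	-10.1	-7.1	120-138	partially (1-5, 7-13)
miR-320d	-19.4	-6.9	-11.1	539-557	partially (1-2, 4-8)
miR-320d	-22.8	-6.9	-12.9	231-249	no
miR-320d	-23.1	-12.3	-11.4	508-526	partially (1-4, 7-8)
miR-320d	-19.2	-6.4	-5.3	714-732	no
miR-483-5p	-24.7	-9.8	-6.8	122-143	no
miR-483-5p	-24.1	-7.6	-6.3	708-729	no
miR-574-3p	-27.8	-8.6	-5.3	725-746	yes
miR-574-3p	-32.5	-7.3	-9.7	37-58	partially (2-5, 7-13)
miR-574-5p	-22.7	-7.3	-11.0	465-487	yes
miR-574-5p	-25.6	-14.5	-14.1	664-686	no
miR-574-5p	-30.2	-12.5	-0.3	740-762	no
miR-574-5p	-22.9	-8.0	-12.3	413-435	no
miR-574-5p	-21.6	-7.8	-11.1	364-386	no
miR-140-3p	-19.1	-11.3	0.3	746-766	partially (1-4)
miR-140-3p	-20.2	-7.3	-9.7	38-58	yes
miR-140-3p	-24.2	-7.7	-5.3	713-733	yes
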